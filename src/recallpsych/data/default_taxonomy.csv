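story,item,category
A,1,proper_name
A,2,proper_name
A,3,other
A,4,proper_name
A,5,other
A,6,verb
A,7,other
A,8,number
A,9,verb
A,10,other
A,11,number
A,12,other
A,13,verb
A,14,other
A,15,proper_name
A,16,other
A,17,verb
A,18,other
A,19,verb
A,20,other
A,21,proper_name
A,22,verb
A,23,other
A,24,verb
A,25,other
B,1,proper_name
B,2,other
B,3,proper_name
B,4,verb
B,5,other
B,6,number
B,7,verb
B,8,other
B,9,verb
B,10,proper_name
B,11,other
B,12,verb
B,13,other
B,14,number
B,15,verb
B,16,other
B,17,other
B,18,verb
B,19,other
B,20,proper_name
B,21,other
B,22,verb
B,23,other
B,24,other
B,25,other
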