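# weighted=true
group,factor,class,share_percent
environment,R1,Fatal,1.4
environment,R1,Injury,4.1
environment,R1,Property,2.9
environment,R2,Fatal,15.1
environment,R2,Injury,4.4
environment,R2,Property,3.1
environment,R3,Fatal,13.6
environment,R3,Injury,17.5
environment,R3,Property,9.7
environment,R4,Fatal,7.8
environment,R4,Injury,11.3
environment,R4,Property,6.2
driver_state,R5,Fatal,14.3
driver_state,R5,Injury,2.9
driver_state,R5,Property,1.0
driver_state,R6,Fatal,1.1
driver_state,R6,Injury,0.6
driver_state,R6,Property,0.3
driver_behavior,R7,Fatal,12.2
driver_behavior,R7,Injury,3.9
driver_behavior,R7,Property,1.8
driver_behavior,R8,Fatal,7.4
driver_behavior,R8,Injury,1.2
driver_behavior,R8,Property,0.2
driver_behavior,R9,Fatal,4.1
driver_behavior,R9,Injury,4.9
driver_behavior,R9,Property,3.0
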