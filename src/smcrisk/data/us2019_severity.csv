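class,consequence,avg_cost,count
Fatal,Fatal,1565000,33244
Major,Injury,20235,1916000
Minor,Property,4711,4806000
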