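block,Batch,Storage,Technician,Mixer,25,50,75,100
01,Milk A,Storage A,Technician 1,Mixer A,23.9,51.9,74.9,100.9
02,Milk A,Storage A,Technician 2,Mixer B,24.3,50.5,74.2,99.3
03,Milk A,Storage B,Technician 1,Mixer B,24.8,49.9,73.6,97.6
04,Milk A,Storage B,Technician 2,Mixer A,29.2,55.3,79.4,102.7
05,Milk B,Storage B,Technician 2,Mixer B,28.4,53.4,78.3,103.1
06,Milk B,Storage B,Technician 1,Mixer A,26.5,51.3,77.9,101.8
07,Milk B,Storage A,Technician 2,Mixer A,25.0,52.9,77.2,102.1
08,Milk B,Storage A,Technician 1,Mixer B,25.5,51.7,74.3,98.4
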