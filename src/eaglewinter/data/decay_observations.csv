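species,temperature_C,k_per_day,exposure,source
Chum salmon,-0.5,-0.0018,Air,ChumDecompStudy
Rainbow trout,4.2,-0.0155,Water,TroutStreamStudyA
Chum salmon,4.3,-0.0314,Air,ChumDecompStudy
Rainbow trout,4.4,-0.0210,Water,TroutStreamStudyB
Chum salmon,8.0,-0.0236,Water,ChumDecompStudy
Chum salmon,8.0,-0.0358,Water,ChumDecompStudy
Rainbow trout,8.6,-0.0479,Water,TroutStreamStudyA
Pink salmon,9.5,-0.0330,Water,PinkCarcassStudy
Rainbow trout,16.0,-0.0570,Water,TroutStreamStudyC
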