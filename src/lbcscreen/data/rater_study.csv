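case_id,report,CS1,CS2,CS3,CS4,CS5,CS6,CS7,CS8,CS9,CS10,CS11,CS12,CS13,CS14,CS15,CS16
case01,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM
case02,NILM,NILM,NILM,NILM,NILM,NILM,ASC-US,NILM,NILM,NILM,NILM,NILM,ASC-US,NILM,NILM,NILM,NILM
case03,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,ASC-H,HSIL,LSIL,NILM,NILM
case04,NILM,NILM,ASC-H,NILM,ASC-US,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,ASC-US
case05,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,ASC-H,NILM,NILM,NILM,NILM,LSIL
case06,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM
case07,NILM,NILM,HSIL,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,NILM,LSIL,NILM
case08,NILM,NILM,ASC-H,ASC-US,ASC-US,NILM,NILM,NILM,NILM,NILM,NILM,HSIL,LSIL,ASC-US,NILM,NILM,ASC-US
case09,HSIL,HSIL,HSIL,HSIL,HSIL,HSIL,HSIL,HSIL,HSIL,HSIL,LSIL,LSIL,SCC,HSIL,HSIL,HSIL,HSIL
case10,LSIL,ASC-H,HSIL,LSIL,SCC,ASC-US,HSIL,ASC-H,ASC-US,LSIL,LSIL,HSIL,HSIL,ASC-H,LSIL,ASC-US,SCC
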