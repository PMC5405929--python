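PATIENT_ID,DATE,PERDAY,CATEGORY,DURATION
37,04/10/2036,4,medA,50
37,07/30/2036,4,medA,50
37,09/15/2036,4,medA,50
37,01/02/2037,4,medB,30
37,01/31/2037,4,medB,30
37,05/09/2037,4,medB,30
37,08/13/2037,4,medB,30
37,11/09/2037,4,medB,30
76,12/13/2035,20,medA,30
76,01/18/2036,20,medA,30
76,01/23/2036,2,medA,60
76,04/25/2036,2,medA,60
76,08/08/2036,2,medA,60
76,10/03/2036,2,medA,60
76,11/29/2036,2,medA,60
76,12/21/2036,6,medB,30
76,01/05/2037,6,medB,30
76,07/13/2037,6,medB,30
76,10/11/2037,2,medA,30
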