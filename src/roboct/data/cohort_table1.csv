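patient_id,gender,race,age,eye,health,device,mean_um,sd_um
1,Female,Black,55,OD,healthy,RAOCT,297,0.6
1,Female,Black,55,OS,healthy,RAOCT,286,1.5
1,Female,Black,55,OD,healthy,Spectralis,293,1.0
1,Female,Black,55,OS,healthy,Spectralis,279,1.0
2,Female,White,28,OD,healthy,RAOCT,250,0.6
2,Female,White,28,OS,healthy,RAOCT,253,1.2
2,Female,White,28,OD,healthy,Spectralis,255,7.8
2,Female,White,28,OS,healthy,Spectralis,251,0.6
3,Female,Black,49,OD,healthy,RAOCT,273,0.6
3,Female,Black,49,OS,healthy,RAOCT,265,1.0
3,Female,Black,49,OD,healthy,Spectralis,275,1.5
3,Female,Black,49,OS,healthy,Spectralis,272,0.6
4,Female,White,46,OD,healthy,RAOCT,263,0.6
4,Female,White,46,OS,healthy,RAOCT,262,0.6
4,Female,White,46,OD,healthy,Spectralis,266,2.1
4,Female,White,46,OS,healthy,Spectralis,268,0.6
5,Male,White,57,OD,healthy,RAOCT,287,1.0
5,Male,White,57,OS,healthy,RAOCT,283,1.2
5,Male,White,57,OD,healthy,Spectralis,287,2.0
5,Male,White,57,OS,healthy,Spectralis,291,3.5
6,Male,White,57,OD,healthy,RAOCT,301,1.0
6,Male,White,57,OS,healthy,RAOCT,308,1.0
6,Male,White,57,OD,healthy,Spectralis,296,2.1
6,Male,White,57,OS,healthy,Spectralis,305,1.5
7,Male,White,36,OD,healthy,RAOCT,313,0.6
7,Male,White,36,OS,healthy,RAOCT,316,0.6
7,Male,White,36,OD,healthy,Spectralis,309,2.3
7,Male,White,36,OS,healthy,Spectralis,304,4.6
8,Female,Asian,25,OD,healthy,RAOCT,264,1.0
8,Female,Asian,25,OS,healthy,RAOCT,262,1.2
8,Female,Asian,25,OD,healthy,Spectralis,278,5.5
8,Female,Asian,25,OS,healthy,Spectralis,271,1.7
9,Male,White,83,OD,healthy,RAOCT,312,1.2
9,Male,White,83,OS,healthy,RAOCT,317,0.6
9,Male,White,83,OD,healthy,Spectralis,317,2.1
9,Male,White,83,OS,healthy,Spectralis,322,1.7
10,Female,White,34,OD,healthy,RAOCT,275,0.0
10,Female,White,34,OS,healthy,RAOCT,269,0.0
10,Female,White,34,OD,healthy,Spectralis,271,0.0
10,Female,White,34,OS,healthy,Spectralis,264,1.5
11,Female,White,91,OD,diseased,RAOCT,284,1.2
11,Female,White,91,OD,diseased,Spectralis,285,3.5
12,Female,White,49,OD,diseased,RAOCT,293,1.5
12,Female,White,49,OS,diseased,RAOCT,295,2.1
12,Female,White,49,OD,diseased,Spectralis,286,1.2
12,Female,White,49,OS,diseased,Spectralis,291,3.5
13,Female,White,60,OD,diseased,RAOCT,300,1.5
13,Female,White,60,OD,diseased,Spectralis,302,4.6
14,Female,White,81,OD,diseased,RAOCT,260,2.1
14,Female,White,81,OS,diseased,RAOCT,228,4.6
14,Female,White,81,OD,diseased,Spectralis,265,3.8
14,Female,White,81,OS,diseased,Spectralis,228,8.2
15,Female,Black,82,OD,diseased,RAOCT,222,1.2
15,Female,Black,82,OD,diseased,Spectralis,224,4.0
16,Male,White,69,OS,diseased,RAOCT,304,1.2
16,Male,White,69,OS,diseased,Spectralis,322,9.3
17,Male,White,66,OS,diseased,RAOCT,421,1.7
17,Male,White,66,OS,diseased,Spectralis,430,90.0
18,Female,White,81,OD,diseased,RAOCT,572,2.3
18,Female,White,81,OD,diseased,Spectralis,561,17.2
19,Male,White,66,OD,diseased,RAOCT,321,0.6
19,Male,White,66,OS,diseased,RAOCT,280,0.6
19,Male,White,66,OD,diseased,Spectralis,324,17.2
19,Male,White,66,OS,diseased,Spectralis,276,1.0
20,Male,White,76,OS,diseased,RAOCT,286,1.2
20,Male,White,76,OS,diseased,Spectralis,295,3.5
21,Female,White,66,OD,diseased,RAOCT,272,0.6
21,Female,White,66,OS,diseased,RAOCT,283,1.5
21,Female,White,66,OD,diseased,Spectralis,269,5.1
21,Female,White,66,OS,diseased,Spectralis,285,2.1
22,Female,Black,51,OD,diseased,RAOCT,252,1.2
22,Female,Black,51,OS,diseased,RAOCT,249,0.6
22,Female,Black,51,OD,diseased,Spectralis,246,2.1
22,Female,Black,51,OS,diseased,Spectralis,246,3.6
23,Female,Black,76,OS,diseased,RAOCT,305,1.5
23,Female,Black,76,OS,diseased,Spectralis,326,19.6
24,Male,White,71,OD,diseased,RAOCT,474,8.9
24,Male,White,71,OS,diseased,RAOCT,276,2.0
24,Male,White,71,OD,diseased,Spectralis,454,14.7
24,Male,White,71,OS,diseased,Spectralis,277,5.6
25,Female,White,43,OD,diseased,RAOCT,274,4.4
25,Female,White,43,OS,diseased,RAOCT,361,1.2
25,Female,White,43,OD,diseased,Spectralis,272,2.1
25,Female,White,43,OS,diseased,Spectralis,373,28.7
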