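# betapet-table-version=1
group,beta,reader,general_quality,sharpness,conspicuity,overall
<10 mm,100,1,2,2,2,6
<10 mm,100,2,2,2,2,6
<10 mm,200,1,3,2,3,8
<10 mm,200,2,3,3,3,9
<10 mm,300,1,5,4,4,13
<10 mm,300,2,4,4,4,12
<10 mm,400,1,4,3,4,11
<10 mm,400,2,4,3,4,11
<10 mm,500,1,3,3,3,9
<10 mm,500,2,3,3,3,9
<10 mm,600,1,2,3,2,7
<10 mm,600,2,2,3,2,7
<10 mm,700,1,1,2,1,4
<10 mm,700,2,1,2,1,4
<10 mm,800,1,1,1,1,3
<10 mm,800,2,1,1,1,3
<10 mm,900,1,1,1,1,3
<10 mm,900,2,1,1,1,3
<10 mm,1000,1,1,1,1,3
<10 mm,1000,2,1,1,1,3
10-30 mm,100,1,1,2,1.5,4.5
10-30 mm,100,2,1,2,1.5,4.5
10-30 mm,200,1,2,2,2,6
10-30 mm,200,2,2.5,2,2,6.5
10-30 mm,300,1,3,3.5,3,9.5
10-30 mm,300,2,3,3.5,4,10.5
10-30 mm,400,1,4,4,4,12
10-30 mm,400,2,4,4,4,12
10-30 mm,500,1,3,3,3,9
10-30 mm,500,2,3,3,3,9
10-30 mm,600,1,2,2.5,2,6.5
10-30 mm,600,2,2,2.5,2,6.5
10-30 mm,700,1,2,2,2,6
10-30 mm,700,2,1.5,2,1,4.5
10-30 mm,800,1,1,1,1,3
10-30 mm,800,2,1,1,1,3
10-30 mm,900,1,1,1,1,3
10-30 mm,900,2,1,1,1,3
10-30 mm,1000,1,1,1,1,3
10-30 mm,1000,2,1,1,1,3
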