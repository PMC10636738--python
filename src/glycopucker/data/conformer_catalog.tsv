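# label	theta_ref	phi_ref	family  (degrees; generated by generate_conformer_catalog(Q_ref=0.55))
4C1	0.000000000	0.000000000	chair
1C4	180.000000000	0.000000000	chair
1,4B	90.000000000	240.000000000	boat
B1,4	90.000000000	60.000000000	boat
2,5B	90.000000000	120.000000000	boat
B2,5	90.000000000	300.000000000	boat
O,3B	90.000000000	0.000000000	boat
B3,O	90.000000000	180.000000000	boat
1S3	90.000000000	210.000000000	twist-boat
3S1	90.000000000	30.000000000	twist-boat
1S5	90.000000000	270.000000000	twist-boat
5S1	90.000000000	90.000000000	twist-boat
2SO	90.000000000	150.000000000	twist-boat
OS2	90.000000000	330.000000000	twist-boat
OE	54.735610317	0.000000000	envelope
EO	125.264389683	180.000000000	envelope
1E	125.264389683	240.000000000	envelope
E1	54.735610317	60.000000000	envelope
2E	54.735610317	120.000000000	envelope
E2	125.264389683	300.000000000	envelope
3E	125.264389683	0.000000000	envelope
E3	54.735610317	180.000000000	envelope
4E	54.735610317	240.000000000	envelope
E4	125.264389683	60.000000000	envelope
5E	125.264389683	120.000000000	envelope
E5	54.735610317	300.000000000	envelope
OH1	50.768479516	30.000000000	half-chair
1HO	129.231520484	210.000000000	half-chair
1H2	129.231520484	270.000000000	half-chair
2H1	50.768479516	90.000000000	half-chair
2H3	50.768479516	150.000000000	half-chair
3H2	129.231520484	330.000000000	half-chair
3H4	129.231520484	30.000000000	half-chair
4H3	50.768479516	210.000000000	half-chair
4H5	50.768479516	270.000000000	half-chair
5H4	129.231520484	90.000000000	half-chair
5HO	129.231520484	150.000000000	half-chair
OH5	50.768479516	330.000000000	half-chair
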