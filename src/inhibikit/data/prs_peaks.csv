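peak_id,tr_min,lambda_max,detected_mz,calculated_mz,ppm,formula,identification,area_control,area_treated
1,3.75,296;263;220,497.1292,497.1295,-0.6,C22H26O13,Verproside,112306,61907
2,4.84,296;263;220,533.1068,533.1062,1.1,C22H27ClO13,Longifolioside A,10677,3852
3,5.39,258,481.1327,481.1346,-3.9,C22H26O12,Catalposide,26121,21250
4,5.88,328;218,523.1436,523.1452,-3.1,C24H28O13,Verminoside,16481,2886
5,6.01,294;263;220,511.1451,511.1452,-0.2,C23H28O13,Picroside II,17798,12194
6,6.10,296;263;220,533.1064,533.1062,0.4,C22H27ClO13,Piscroside C,44999,22171
7,6.42,296;263;220,511.1447,511.1452,-0.1,C23H28O13,Isovanillyl catapol,12844,8093
8,9.04,327;220,537.1647,537.1608,7.3,C25H30O13,Minecoside,976,465
9,9.17,328;220,525.1627,525.1613,2.5,C24H30O13,6-O-Veratroyl catalpol,15756,11932
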