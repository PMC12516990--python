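# name: toy_linear
# source: closed form: 1 - 0.1 * sum(level - 1)
# range: [0.0, 1.0]
state_code,utility
11111,1.0
11112,0.9
11113,0.8
11121,0.9
11122,0.8
11123,0.7
11131,0.8
11132,0.7
11133,0.6
11211,0.9
11212,0.8
11213,0.7
11221,0.8
11222,0.7
11223,0.6
11231,0.7
11232,0.6
11233,0.5
11311,0.8
11312,0.7
11313,0.6
11321,0.7
11322,0.6
11323,0.5
11331,0.6
11332,0.5
11333,0.4
12111,0.9
12112,0.8
12113,0.7
12121,0.8
12122,0.7
12123,0.6
12131,0.7
12132,0.6
12133,0.5
12211,0.8
12212,0.7
12213,0.6
12221,0.7
12222,0.6
12223,0.5
12231,0.6
12232,0.5
12233,0.4
12311,0.7
12312,0.6
12313,0.5
12321,0.6
12322,0.5
12323,0.4
12331,0.5
12332,0.4
12333,0.3
13111,0.8
13112,0.7
13113,0.6
13121,0.7
13122,0.6
13123,0.5
13131,0.6
13132,0.5
13133,0.4
13211,0.7
13212,0.6
13213,0.5
13221,0.6
13222,0.5
13223,0.4
13231,0.5
13232,0.4
13233,0.3
13311,0.6
13312,0.5
13313,0.4
13321,0.5
13322,0.4
13323,0.3
13331,0.4
13332,0.3
13333,0.2
21111,0.9
21112,0.8
21113,0.7
21121,0.8
21122,0.7
21123,0.6
21131,0.7
21132,0.6
21133,0.5
21211,0.8
21212,0.7
21213,0.6
21221,0.7
21222,0.6
21223,0.5
21231,0.6
21232,0.5
21233,0.4
21311,0.7
21312,0.6
21313,0.5
21321,0.6
21322,0.5
21323,0.4
21331,0.5
21332,0.4
21333,0.3
22111,0.8
22112,0.7
22113,0.6
22121,0.7
22122,0.6
22123,0.5
22131,0.6
22132,0.5
22133,0.4
22211,0.7
22212,0.6
22213,0.5
22221,0.6
22222,0.5
22223,0.4
22231,0.5
22232,0.4
22233,0.3
22311,0.6
22312,0.5
22313,0.4
22321,0.5
22322,0.4
22323,0.3
22331,0.4
22332,0.3
22333,0.2
23111,0.7
23112,0.6
23113,0.5
23121,0.6
23122,0.5
23123,0.4
23131,0.5
23132,0.4
23133,0.3
23211,0.6
23212,0.5
23213,0.4
23221,0.5
23222,0.4
23223,0.3
23231,0.4
23232,0.3
23233,0.2
23311,0.5
23312,0.4
23313,0.3
23321,0.4
23322,0.3
23323,0.2
23331,0.3
23332,0.2
23333,0.1
31111,0.8
31112,0.7
31113,0.6
31121,0.7
31122,0.6
31123,0.5
31131,0.6
31132,0.5
31133,0.4
31211,0.7
31212,0.6
31213,0.5
31221,0.6
31222,0.5
31223,0.4
31231,0.5
31232,0.4
31233,0.3
31311,0.6
31312,0.5
31313,0.4
31321,0.5
31322,0.4
31323,0.3
31331,0.4
31332,0.3
31333,0.2
32111,0.7
32112,0.6
32113,0.5
32121,0.6
32122,0.5
32123,0.4
32131,0.5
32132,0.4
32133,0.3
32211,0.6
32212,0.5
32213,0.4
32221,0.5
32222,0.4
32223,0.3
32231,0.4
32232,0.3
32233,0.2
32311,0.5
32312,0.4
32313,0.3
32321,0.4
32322,0.3
32323,0.2
32331,0.3
32332,0.2
32333,0.1
33111,0.6
33112,0.5
33113,0.4
33121,0.5
33122,0.4
33123,0.3
33131,0.4
33132,0.3
33133,0.2
33211,0.5
33212,0.4
33213,0.3
33221,0.4
33222,0.3
33223,0.2
33231,0.3
33232,0.2
33233,0.1
33311,0.4
33312,0.3
33313,0.2
33321,0.3
33322,0.2
33323,0.1
33331,0.2
33332,0.1
33333,0.0
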