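goal_id,indicator,increase_is_progress,year,value
1,Population below national poverty line (%),False,2003,50
1,Population below national poverty line (%),False,2006,45
1,Population below national poverty line (%),False,2010,22.1
1,Population below national poverty line (%),False,2014,14
2,Prevalence of undernourishment (%),False,2001,24
2,Prevalence of undernourishment (%),False,2005,17
2,Prevalence of undernourishment (%),False,2010,13
2,Prevalence of undernourishment (%),False,2015,8.9
2,Prevalence of undernourishment (%),False,2019,6.2
3,Under-five mortality rate (per 1000 live births),False,2000,106
3,Under-five mortality rate (per 1000 live births),False,2005,65
3,Under-five mortality rate (per 1000 live births),False,2010,44
3,Under-five mortality rate (per 1000 live births),False,2015,32
3,Under-five mortality rate (per 1000 live births),False,2019,27
3,Children under 5 moderately or severely stunted (%),False,2000,49
3,Children under 5 moderately or severely stunted (%),False,2005,43
3,Children under 5 moderately or severely stunted (%),False,2010,39.8
3,Children under 5 moderately or severely stunted (%),False,2014,32
3,Children under 5 moderately or severely wasted (%),False,2000,17
3,Children under 5 moderately or severely wasted (%),False,2005,8.5
3,Children under 5 moderately or severely wasted (%),False,2010,11
3,Children under 5 moderately or severely wasted (%),False,2014,9.7
4,Completion rate at primary level (%),True,2000,34
4,Completion rate at primary level (%),True,2005,59
4,Completion rate at primary level (%),True,2010,71
4,Completion rate at primary level (%),True,2014,72
4,Completion rate at secondary level (%),True,2000,17
4,Completion rate at secondary level (%),True,2005,27
4,Completion rate at secondary level (%),True,2010,37
4,Completion rate at secondary level (%),True,2014,41
5,Seats held by women in legislative institutions (%),True,2000,8.2
5,Seats held by women in legislative institutions (%),True,2005,9.8
5,Seats held by women in legislative institutions (%),True,2010,21
5,Seats held by women in legislative institutions (%),True,2015,20
5,Seats held by women in legislative institutions (%),True,2019,20
6,Population using safely managed drinking water (%),True,2000,17
6,Population using safely managed drinking water (%),True,2005,19
6,Population using safely managed drinking water (%),True,2010,22
6,Population using safely managed drinking water (%),True,2015,25
6,Population using safely managed drinking water (%),True,2019,27
6,Population with basic handwashing facilities (%),True,2010,63
6,Population with basic handwashing facilities (%),True,2015,67
6,Population with basic handwashing facilities (%),True,2019,73
7,Population with access to electricity (%),True,2000,17
7,Population with access to electricity (%),True,2005,21
7,Population with access to electricity (%),True,2010,31
7,Population with access to electricity (%),True,2015,69
7,Population with access to electricity (%),True,2019,93
8,GDP per capita (current US$),True,2000,301
8,GDP per capita (current US$),True,2005,474
8,GDP per capita (current US$),True,2010,785
8,GDP per capita (current US$),True,2015,1162
8,GDP per capita (current US$),True,2019,1643
9,Population covered by at least a 3G mobile network (%),True,2009,43
9,Population covered by at least a 3G mobile network (%),True,2015,70
9,Population covered by at least a 3G mobile network (%),True,2019,85
10,Gini index of disposable income (0-100),False,2010,37
10,Gini index of disposable income (0-100),False,2015,37
10,Gini index of disposable income (0-100),False,2019,36
11,Urban population living in slums (%),False,2000,79
11,Urban population living in slums (%),False,2014,55
11,Urban population living in slums (%),False,2018,45
12,Domestic material consumption per capita (tonnes),False,2000,2.2
12,Domestic material consumption per capita (tonnes),False,2005,2.7
12,Domestic material consumption per capita (tonnes),False,2010,6.1
12,Domestic material consumption per capita (tonnes),False,2015,4.9
12,Domestic material consumption per capita (tonnes),False,2017,5.3
13,Domestic fossil fuel consumption per capita (tonnes),False,2000,0.1
13,Domestic fossil fuel consumption per capita (tonnes),False,2005,0.1
13,Domestic fossil fuel consumption per capita (tonnes),False,2010,0.1
13,Domestic fossil fuel consumption per capita (tonnes),False,2015,0.2
13,Domestic fossil fuel consumption per capita (tonnes),False,2017,0.2
14,Sustainable fisheries as a proportion of GDP (%),True,2011,1.1
14,Sustainable fisheries as a proportion of GDP (%),True,2015,0.8
14,Sustainable fisheries as a proportion of GDP (%),True,2017,0.6
15,Forest area as a proportion of total land area (%),True,2000,61
15,Forest area as a proportion of total land area (%),True,2005,60
15,Forest area as a proportion of total land area (%),True,2010,50
15,Forest area as a proportion of total land area (%),True,2015,46
16,Voice and Accountability index (-2.5 to 2.5),True,2000,-0.8
16,Voice and Accountability index (-2.5 to 2.5),True,2005,-1.0
16,Voice and Accountability index (-2.5 to 2.5),True,2010,-0.9
16,Voice and Accountability index (-2.5 to 2.5),True,2015,-1.1
16,Voice and Accountability index (-2.5 to 2.5),True,2019,-1.2
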