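id,name,definition,aliases
1,No poverty,End poverty in all its forms everywhere.,
2,Zero hunger,"End hunger, achieve food security and improved nutrition and promote sustainable agriculture.",
3,Child health,"Complete physical, mental and social well-being, and not merely the absence of disease or infirmity, among human beings below 18 years.",CH
4,Quality education,Ensure inclusive and equitable quality education and promote lifelong learning opportunities for all.,
5,Gender equality,Achieve gender equality and empower all women and girls.,
6,Clean water and sanitation,Ensure availability and sustainable management of water and sanitation for all.,
7,Affordable and clean energy,"Ensure access to affordable, reliable, sustainable and modern energy for all.",
8,Decent work and economic growth,"Promote sustained, inclusive and sustainable economic growth, full and productive employment and decent work for all.",
9,"Industry, innovation and infrastructure","Build resilient infrastructure, promote inclusive and sustainable industrialization and foster innovation.",
10,Reduced inequalities,Reduce inequality within and among countries.,
11,Sustainable cities and communities,"Make cities and human settlements inclusive, safe, resilient and sustainable.",
12,Responsible consumption and production,Ensure sustainable consumption and production patterns.,
13,Climate action,Take urgent action to combat climate change and its impacts.,
14,Life below water,"Conserve and sustainably use the oceans, seas and marine resources for sustainable development.",
15,Life on land,"Protect, restore and promote sustainable use of terrestrial ecosystems, sustainably manage forests, combat desertification, and halt and reverse land degradation and halt biodiversity loss.",
16,"Peace, justice and strong institutions","Promote peaceful and inclusive societies for sustainable development, provide access to justice for all and build effective, accountable and inclusive institutions at all levels.",
18,Mine/ERW free,End the negative impact of mine and explosive remnants of war and promote victim assistance.,
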