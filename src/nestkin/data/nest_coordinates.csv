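# nestkin fixture: planar coordinates (projected metres) of 20 low solitary nests; one nest per tree
nest,x,y,nests_on_tree
1,584212.23,551979.28,1
2,585361.07,551090.93,1
3,584449.37,551973.10,1
4,583015.41,556065.82,1
5,578453.71,558196.83,1
6,581476.68,560048.02,1
7,584303.09,555828.73,1
8,581075.12,557498.23,1
9,590707.35,544311.77,1
10,581651.14,557439.59,1
11,581108.79,556896.12,1
12,583409.25,554716.91,1
13,583095.50,556114.89,1
14,593358.41,538489.08,1
15,583132.63,556317.61,1
16,593108.59,537899.25,1
17,583905.88,556283.56,1
18,576381.47,560296.06,1
19,583083.15,556010.49,1
20,582379.28,552542.33,1
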