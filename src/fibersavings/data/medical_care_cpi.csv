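year,index
2000,260.8
2001,272.8
2002,285.6
2003,297.1
2004,310.1
2005,323.2
2006,336.2
2007,351.1
2008,364.1
2009,375.6
2010,388.4
2011,400.3
2012,414.9
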