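colony,year,count,kind,count_day
guadalupe,1965,3668,pup_feb,
guadalupe,1969,7104,pup_feb,
guadalupe,1970,5520,pup_feb,
guadalupe,1975,6058,pup_feb,
guadalupe,1977,5642,pup_feb,
guadalupe,1978,5552,pup_feb,
guadalupe,1980,5011,pup_feb,
guadalupe,1982,4760,pup_feb,
guadalupe,1991,4962,pup_feb,
guadalupe,2005,3785,pup_feb,
guadalupe,2009,3074,female_jan,
guadalupe,2010,3150,female_jan,
guadalupe,2015,2037,female_jan,
san_benito,1965,800,pup_feb,
san_benito,1970,1578,pup_feb,
san_benito,1975,815,pup_feb,
san_benito,1977,1359,pup_feb,
san_benito,1978,1727,pup_feb,
san_benito,1980,1752,pup_feb,
san_benito,1991,1662,pup_feb,
san_benito,2001,1849,pup_feb,
san_benito,2002,2024,pup_feb,
san_benito,2003,2050,pup_feb,
san_benito,2004,1771,pup_feb,
san_benito,2009,1689,female_jan,
san_benito,2013,1504,pup_feb,
san_benito,2014,1097,pup_feb,
san_benito,2015,1205,pup_feb,
san_benito,2016,1317,pup_feb,
cedros,1965,0,pup_feb,
cedros,1970,49,pup_feb,
cedros,1977,112,pup_feb,
cedros,1985,166,pup_feb,
cedros,1988,227,pup_feb,
cedros,1991,391,pup_feb,
cedros,2005,304,pup_feb,
cedros,2009,411,pup_feb,
cedros,2010,339,pup_feb,
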