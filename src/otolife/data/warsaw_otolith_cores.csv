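sample_id,analysis_id,tl_mm,oto_mass_mg,sample_date,printed_year_of_formation,age_years,d13c,d14c,d14c_sd
WRG-1,OS-93156,1158,0.389,08/21/1980,1966,14,-2.84,122.06,5.0
WRG-2,OS-93154,942,0.307,04/22/1991,1986,5,-4.92,107.59,4.7
WRG-3,OS-93155,1007,0.350,06/05/1991,1987,4,-3.61,103.77,4.7
WRG-4,OS-93085,1007,0.416,01/07/1992,1988,4,-4.05,121.73,5.1
WRG-5,OS-93300,1760,1.557,06/10/2000,1975,25,-4.15,139.05,5.3
WRG-6,OS-93157,1442,0.862,09/05/2004,1996,8,-2.71,102.42,4.8
WRG-7,OS-94285,1206,0.500,10/18/2009,2002,5,-3.24,62.98,3.1
WRG-0022,OS-132877,203,0.021,12/22/2005,2008,1,-4.46,52.73,2.2
WRG-0403,OS-133006,2134,1.979,04/22/2005,1956,49,-1.73,-42.7,1.9
WRG-1465,OS-133007,1805,1.591,12/12/2013,1964,41,-1.94,43.51,2.1
WRG-3201,OS-133008,1994,--,12/12/2013,1968,45,-1.91,123.94,2.3
WRG-3203,OS-133009,1403,--,12/12/2013,2002,11,-3.78,71.74,2.1
WRG-0675,OS-138429,1954,1.956,02/09/2017,1958,59,NM,-60.72,2.1
WRG-17-SPO,OS-138430,2186,2.447,08/19/2017,1963,54,-2.97,59.29,2.2
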