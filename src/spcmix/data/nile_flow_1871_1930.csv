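label,value
1871,1120
1872,1160
1873,963
1874,1210
1875,1160
1876,1160
1877,813
1878,1230
1879,1370
1880,1140
1881,995
1882,935
1883,1110
1884,994
1885,1020
1886,960
1887,1180
1888,799
1889,958
1890,1140
1891,1100
1892,1210
1893,1150
1894,1250
1895,1260
1896,1220
1897,1030
1898,1100
1899,774
1900,840
1901,874
1902,694
1903,940
1904,833
1905,701
1906,916
1907,692
1908,1020
1909,1050
1910,969
1911,831
1912,726
1913,456
1914,824
1915,702
1916,1120
1917,1100
1918,832
1919,764
1920,821
1921,768
1922,845
1923,864
1924,862
1925,698
1926,845
1927,744
1928,796
1929,1040
1930,759
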