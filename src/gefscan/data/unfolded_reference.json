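{
 "A": 5.409514,
 "C": 4.57531,
 "D": 9.807766,
 "E": 6.982901,
 "F": 11.443901,
 "G": 2.928025,
 "H": 4.196414,
 "I": 11.987316,
 "K": 4.323194,
 "L": 8.066899,
 "M": 4.259552,
 "N": 8.698377,
 "P": 17.29669,
 "Q": 6.213652,
 "R": 5.544707,
 "S": 5.725774,
 "T": 9.624897,
 "V": 11.656226,
 "W": 9.56527,
 "Y": 11.350909
}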