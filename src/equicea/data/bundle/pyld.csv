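ethnicity,sex,age_band,value
maori,female,45-49,0.134
maori,female,50-54,0.164
maori,female,55-59,0.194
maori,female,60-64,0.224
maori,female,65-69,0.254
maori,female,70-74,0.28400000000000003
maori,female,75-79,0.314
maori,female,80-84,0.34400000000000003
maori,female,85-89,0.374
maori,female,90-94,0.40399999999999997
maori,male,45-49,0.1266
maori,male,50-54,0.15360000000000001
maori,male,55-59,0.1806
maori,male,60-64,0.2076
maori,male,65-69,0.2346
maori,male,70-74,0.2616
maori,male,75-79,0.28859999999999997
maori,male,80-84,0.31560000000000005
maori,male,85-89,0.3426
maori,male,90-94,0.3696
non_maori,female,45-49,0.07400000000000001
non_maori,female,50-54,0.10400000000000001
non_maori,female,55-59,0.134
non_maori,female,60-64,0.164
non_maori,female,65-69,0.194
non_maori,female,70-74,0.224
non_maori,female,75-79,0.254
non_maori,female,80-84,0.28400000000000003
non_maori,female,85-89,0.314
non_maori,female,90-94,0.344
non_maori,male,45-49,0.0666
non_maori,male,50-54,0.09360000000000002
non_maori,male,55-59,0.12060000000000001
non_maori,male,60-64,0.1476
non_maori,male,65-69,0.1746
non_maori,male,70-74,0.2016
non_maori,male,75-79,0.2286
non_maori,male,80-84,0.25560000000000005
non_maori,male,85-89,0.2826
non_maori,male,90-94,0.3096
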