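ethnicity,sex,age_band,count
maori,female,45-49,7642.0
maori,female,50-54,5625.0
maori,female,55-59,3995.0
maori,female,60-64,3115.0
maori,female,65-69,2248.0
maori,female,70-74,1681.0
maori,female,75-79,1242.0
maori,female,80-84,914.0
maori,female,85-89,678.0
maori,female,90-94,503.0
maori,male,45-49,7548.0
maori,male,50-54,5674.0
maori,male,55-59,4095.0
maori,male,60-64,3079.0
maori,male,65-69,2286.0
maori,male,70-74,1683.0
maori,male,75-79,1240.0
maori,male,80-84,919.0
maori,male,85-89,684.0
maori,male,90-94,489.0
non_maori,female,45-49,60663.0
non_maori,female,50-54,51416.0
non_maori,female,55-59,42743.0
non_maori,female,60-64,36144.0
non_maori,female,65-69,29236.0
non_maori,female,70-74,25087.0
non_maori,female,75-79,20597.0
non_maori,female,80-84,18413.0
non_maori,female,85-89,14684.0
non_maori,female,90-94,12811.0
non_maori,male,45-49,58427.0
non_maori,male,50-54,51253.0
non_maori,male,55-59,41361.0
non_maori,male,60-64,34914.0
non_maori,male,65-69,31004.0
non_maori,male,70-74,25182.0
non_maori,male,75-79,21467.0
non_maori,male,80-84,17483.0
non_maori,male,85-89,15001.0
non_maori,male,90-94,12717.0
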