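age_band,sex,annual_cost,last_six_months_cost
45-49,female,1200.0,25000.0
45-49,male,1200.0,25000.0
50-54,female,1429.5,25000.0
50-54,male,1429.5,25000.0
55-59,female,1702.88,25000.0
55-59,male,1702.88,25000.0
60-64,female,2028.55,25000.0
60-64,male,2028.55,25000.0
65-69,female,2416.5,25000.0
65-69,male,2416.5,25000.0
70-74,female,2878.65,25000.0
70-74,male,2878.65,25000.0
75-79,female,3429.18,25000.0
75-79,male,3429.18,25000.0
80-84,female,4085.0,25000.0
80-84,male,4085.0,25000.0
85-89,female,4866.24,25000.0
85-89,male,4866.24,25000.0
90-94,female,5796.89,25000.0
90-94,male,5796.89,25000.0
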