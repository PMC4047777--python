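cancer,phase,monthly_cost
lung,diagnosis,6000.0
lung,preterminal,4000.0
lung,remission,250.0
lung,terminal,9000.0
breast,diagnosis,5000.0
breast,preterminal,3500.0
breast,remission,200.0
breast,terminal,8500.0
colon,diagnosis,5500.0
colon,preterminal,3800.0
colon,remission,220.0
colon,terminal,8800.0
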