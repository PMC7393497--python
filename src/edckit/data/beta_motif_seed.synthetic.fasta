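>beta_seed_1 synthetic
LPVCKPVAVSGNEPIVSGGYGSPYATRVVGGDLG
>beta_seed_2 synthetic
LPVCKPVAVSGKEPIVSGGYGSPYATRVWFQDLG
>beta_seed_3 synthetic
LPVCKFVAVSGNECIVSGGYGSPYATRVVEGDLG
>beta_seed_4 synthetic
LPVCKPWAVSSNEPIVSGGYGSPYATRVVGSDLG
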