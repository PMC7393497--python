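>s100_seed_1 synthetic
MALEKSLDTVIGIFHKYAGQDGDKSTLSKKELKQLLQSEFGDILENPKDPATVDKILHDLDANKDGEVSFEEFVVLVSRVL
>s100_seed_2 synthetic
MALEKVCDTVIGIFHIYAGQDGDKSTLWKKELKQLLQSEFGDILANPKDPATVDKIHHDLDANKDGEVPFEEFVVLVSRVL
>s100_seed_3 synthetic
MALEKFLDTVIGIFHKYAGQDGDKSTLSKKVIKQLLQSEGGDILENPKDPATVDKILHILDANKYCMVSFEEFVVLVSRVL
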