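variant_id,pub_median,pub_lower,pub_upper,calc_median,calc_lower,calc_upper
1q21.1_del,0.061,0.03,0.12,0.061,0.02,0.16
2p16.3_del,0.020,0.01,0.04,0.021,0.01,0.04
15q11.2_del,0.020,0.01,0.03,0.020,0.01,0.03
15q13.3_del,0.074,0.03,0.16,0.074,0.03,0.21
16p13.1_dup,0.024,0.01,0.04,0.024,0.01,0.05
16p11.2_dup,0.069,0.03,0.14,0.069,0.03,0.18
17p12_del,0.067,0.03,0.17,0.067,0.02,0.24
22q11_del,0.553,0.18,0.97,0.553,0.12,1.0
1q21.1_dup_proximal,0.173,0.11,0.27,0.165,0.08,0.32
1q21.1_del_distal,0.369,0.23,0.55,0.346,0.18,0.61
1q21.1_dup_distal,0.291,0.17,0.47,0.271,0.13,0.53
15q11.2_del_2,0.104,0.08,0.13,0.103,0.08,0.14
16p13.11_del,0.131,0.79,0.21,0.126,0.06,0.26
16p12.1_del,0.123,0.79,0.19,0.120,0.06,0.23
16p11.2_del_distal,0.624,0.27,0.94,0.501,0.18,0.93
16p11.2_dup_distal,0.112,0.06,0.20,0.108,0.05,0.25
16p11.2_del_proximal,0.468,0.31,0.64,0.443,0.26,0.69
16p11.2_dup_proximal,0.272,0.17,0.41,0.259,0.14,0.47
17q12_del,0.344,0.14,0.70,0.286,0.09,0.73
17q12_dup,0.211,0.10,0.39,0.194,0.08,0.46
22q11.21_dup,0.219,0.15,0.32,0.210,0.12,0.37
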