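# Worked-example parameter sets. c0/rho1 are control-module extras.
example1_case1_I:   {a: 4.0, b: 2.0, c: 0.1, e: 0.7, h: 0.5926274349}
example1_case1_II:  {a: 3.0, b: 2.5, c: 0.2, e: 0.5, h: 1.022801547}
example2_case4_I:   {a: 1.5, b: 0.5, c: 0.1, e: 2.0, h: 3.7328}
example2_case4_II:  {a: 0.5, b: 1.5, c: 0.5, e: 1.2, h: 0.44}
example2_case6_flip: {a: 1.5, b: 0.5, c: 0.09120395559, e: 2.0, h: 3.75}
example2_case6_ns:  {a: 1.5, b: 0.5, c: 0.09942, e: 2.0, h: 3.75}
example3_control:   {a: 9.0, b: 2.0, c: 0.25, e: 0.5, h: 0.5, c0: 0.25, rho1: 1.55}
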