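system,host,role,dg_gaff_submitted,dg_gaff_refined,err_gaff_refined,dg_opls_refined,err_opls_refined,dg_exp
OAMe-G1,OAMe,sampl5,-2.56,-6.36,0.39,-4.74,0.52,-5.36
OAMe-G2,OAMe,sampl5,-2.79,-6.76,0.41,-7.94,0.56,-5.16
OAMe-G3,OAMe,sampl5,-0.84,-5.44,0.56,-3.56,0.45,-5.85
OAMe-G4,OAMe,sampl5,-0.09,-3.64,1.63,-0.36,0.58,-2.38
OAMe-G5,OAMe,sampl5,0.69,-3.45,0.34,-2.43,1.41,-3.91
OAMe-G6,OAMe,sampl5,0.05,-4.28,0.34,-5.30,0.70,-4.49
OAH-G1,OAH,sampl5,-3.08,-6.07,0.35,-6.57,0.35,-5.23
OAH-G2,OAH,sampl5,-2.91,-5.08,0.72,-5.83,0.57,-4.50
OAH-G3,OAH,sampl5,-2.26,-5.92,0.58,-5.99,0.53,-4.79
OAH-G4,OAH,sampl5,-7.94,-11.85,0.61,-11.03,0.61,-9.38
OAH-G5,OAH,sampl5,-1.32,-4.80,0.46,-4.98,0.35,-4.12
OAH-G6,OAH,sampl5,-3.33,-5.52,0.64,-5.94,0.38,-5.13
OAH-Gu2,OAH,reference,-5.90,-9.59,0.66,-7.00,0.87,-5.90
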