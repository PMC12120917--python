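# SYNTHETIC bond-order pair-parameter table for H/C/N/O/F.
#
# This file is a synthetic stand-in: it plays the role of a ReaxFF
# pair-parameter library (reference radii r0_sigma/r0_pi/r0_pipi in Å and
# dimensionless exponents pbo1..pbo6 of the uncorrected bond-order terms
# BO_sigma = exp[pbo1*(r/r0_sigma)^pbo2], BO_pi = exp[pbo3*(r/r0_pi)^pbo4],
# BO_pipi = exp[pbo5*(r/r0_pipi)^pbo6]) with values of realistic magnitude,
# hand-set from typical published ReaxFF CHON parameterizations.  It is NOT
# a transcription of any distributed force field; do not use for physics.
#
# Format: blocks introduced by "pair: A B", followed by key=value lines.
# r0 = -1 marks a term as absent (the term contributes exactly 0).
# Lookup is symmetric: (A, B) and (B, A) resolve to the same block.

pair: H H
r0_sigma=0.656
r0_pi=-1
r0_pipi=-1
pbo1=-0.079
pbo2=6.059
pbo3=0
pbo4=0
pbo5=0
pbo6=0

pair: C H
r0_sigma=1.028
r0_pi=-1
r0_pipi=-1
pbo1=-0.050
pbo2=6.919
pbo3=0
pbo4=0
pbo5=0
pbo6=0

pair: C C
r0_sigma=1.383
r0_pi=1.198
r0_pipi=1.210
pbo1=-0.078
pbo2=6.830
pbo3=-0.100
pbo4=9.264
pbo5=-0.456
pbo6=34.996

pair: N H
r0_sigma=0.976
r0_pi=-1
r0_pipi=-1
pbo1=-0.066
pbo2=6.937
pbo3=0
pbo4=0
pbo5=0
pbo6=0

pair: C N
r0_sigma=1.345
r0_pi=1.189
r0_pipi=1.216
pbo1=-0.106
pbo2=5.795
pbo3=-0.236
pbo4=7.544
pbo5=-0.135
pbo6=29.923

pair: N N
r0_sigma=1.311
r0_pi=1.197
r0_pipi=1.107
pbo1=-0.106
pbo2=5.947
pbo3=-0.244
pbo4=7.535
pbo5=-0.155
pbo6=12.406

pair: O H
r0_sigma=0.913
r0_pi=-1
r0_pipi=-1
pbo1=-0.092
pbo2=5.557
pbo3=0
pbo4=0
pbo5=0
pbo6=0

pair: C O
r0_sigma=1.350
r0_pi=1.149
r0_pipi=1.121
pbo1=-0.142
pbo2=4.767
pbo3=-0.253
pbo4=7.154
pbo5=-0.162
pbo6=12.772

pair: N O
r0_sigma=1.296
r0_pi=1.113
r0_pipi=1.080
pbo1=-0.108
pbo2=5.449
pbo3=-0.257
pbo4=7.037
pbo5=-0.161
pbo6=13.391

pair: O O
r0_sigma=1.245
r0_pi=1.089
r0_pipi=0.995
pbo1=-0.126
pbo2=5.501
pbo3=-0.297
pbo4=7.438
pbo5=-0.178
pbo6=14.986

pair: F H
r0_sigma=0.909
r0_pi=-1
r0_pipi=-1
pbo1=-0.089
pbo2=6.143
pbo3=0
pbo4=0
pbo5=0
pbo6=0

pair: C F
r0_sigma=1.353
r0_pi=-1
r0_pipi=-1
pbo1=-0.117
pbo2=5.640
pbo3=0
pbo4=0
pbo5=0
pbo6=0

pair: N F
r0_sigma=1.370
r0_pi=-1
r0_pipi=-1
pbo1=-0.110
pbo2=5.700
pbo3=0
pbo4=0
pbo5=0
pbo6=0

pair: O F
r0_sigma=1.410
r0_pi=-1
r0_pipi=-1
pbo1=-0.105
pbo2=5.600
pbo3=0
pbo4=0
pbo5=0
pbo6=0

pair: F F
r0_sigma=1.412
r0_pi=-1
r0_pipi=-1
pbo1=-0.100
pbo2=5.500
pbo3=0
pbo4=0
pbo5=0
pbo6=0
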