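"""Point estimates on a tiny tied score sample.

Builds a toy sample of integer similarity scores, discretizes it, and prints
the three operating-point estimates plus the area under the ROC curve.
"""

import rocboot as rb

# four genuine and six impostor scores, with ties within and across classes
sample = rb.ScoreSample(genuine=[3, 3, 2, 1], impostor=[3, 2, 2, 1, 1, 0])
dist = rb.build_distributions(sample)

res = rb.tar_at_far(dist, f=0.25)
print(f"TAR at FAR 0.25      : {res.tar:.4f} (threshold score {res.threshold:g})")
# 0.5625: the genuine mass tied at the threshold is split proportionally, so
# the operating point sits on the ROC polyline exactly at FAR = 0.25

rates = rb.rates_at_threshold(dist, 1.5)
print(f"rates at threshold 1.5: TAR {rates.tar:.4f}, FAR {rates.far:.4f}")
# scores >= 2 are accepted (ceiling rule): 3/4 genuine, 3/6 impostor

eer = rb.eer(dist)
print(f"EER                  : {eer.eer:.4f} over score range [{eer.s1:g}, {eer.s2:g}]")
print(f"  systematic error   : {eer.systematic_error:.2%} of the EER")
# the discreteness of the scores leaves a gap between the two error rates;
# half that gap, relative to the EER, is the systematic error

print(f"AURC                 : {rb.aurc(sample):.4f}")
# 17/24: the probability a random genuine score beats a random impostor
# score, ties counted half
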