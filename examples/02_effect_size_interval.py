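"""Effect size with a noncentral-t confidence interval.

For the same case (0.4 vs controls 0.5 +/- 0.1, n=10) the effect-size
index z_cc = (x - mean)/sd = -1.0. Its 95% interval comes from inverting
the noncentral t distribution at the observed z_cc*sqrt(n), and the
abnormality percentage estimates what fraction of the control population
would score below the case.
"""

import math

from epicase import ControlSummary, effect_size_interval

controls = ControlSummary(mean=0.5, sd=0.1, n=10)
es = effect_size_interval(0.4, controls, confidence=0.95)

print(f"z_cc            = {es.z_cc:+.3f}")
print(f"95% interval    = ({es.ci_lower:+.3f}, {es.ci_upper:+.3f})")
print(f"noncentrality   = {es.ci_lower * math.sqrt(10):+.3f} (lower root)")
print(f"abnormality     = {es.pct_point:.2f}% of controls expected below the case")
print(f"  interval      = ({es.pct_lower:.1f}%, {es.pct_upper:.1f}%)")

# The interval (-1.75, -0.21) excludes 0, yet the abnormality range
# (4%-42%) shows a single case this close to the control mean is not
# diagnostically abnormal — significance and magnitude are different
# questions.
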