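"""Exact duo-trio panel statistics.

A duo-trio panel asks each subject which of two samples matches a
reference; under the null every answer is a fair coin.  With small
panels the exact right-tailed binomial test is appropriate: for 16 of 21
correct the chance probability is about 1.3%, so the panel did perceive
a difference; 4 of 21 is entirely consistent with guessing.
"""

from scentmap import duo_trio_report

for k in (16, 20, 4):
    result = duo_trio_report(k, n=21, p0=0.5, alpha=0.05)
    print(result.verdict())
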