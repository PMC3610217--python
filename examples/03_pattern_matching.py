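"""Convert NLSdb and PROSITE patterns to regular expressions and match them.

The fumarate-lyase family pattern G-S-x(2)-M-x-{RS}-K-x-N is converted to
GS.{2}M.[^RS]K.N and searched in sample segments; coverage is the fraction
of subjects with at least one match.
"""

from discngram import Dialect, convert_pattern, coverage, match_pattern

nls = convert_pattern("KKPx{6,9}Kx{1,3}RK", Dialect.NLSDB)
print(f"NLSdb   {nls.raw}  ->  {nls.converted}")

prosite = convert_pattern("G-S-x(2)-M-x-{RS}-K-x-N", Dialect.PROSITE)
print(f"PROSITE {prosite.raw}  ->  {prosite.converted}")

subjects = [
    "XXPENEPGSSIMPGKVNPTQCXX",
    "GSSAMPYKRNPMRSEXXX",
    "XXEPFEKDQIGSSAMPYKKN",
    "GSSAMPYRKN",  # excluded residue at the {RS} position blocks the match
]
print()
for subject in subjects:
    result = match_pattern(prosite, subject)
    if result.matched:
        start, end = result.spans[0]
        print(f"match    {subject}  [{start}, {end}] = {subject[start - 1:end]}")
    else:
        print(f"no match {subject}")

print(f"\ncoverage: {coverage([prosite], subjects):.2f}")
# 3 of the 4 subjects contain the pattern, so coverage is 0.75.
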