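"""Consolidate syntactically similar n-grams into a token regular expression.

Groups of n-grams sharing their first and last tokens are aligned
(Needleman-Wunsch) and merged: columns where all members agree stay
literal, disagreeing runs become alternations, members missing a run make
it optional.  The induced expression matches every member and typically
pools their support into a stronger meta-feature.
"""

from patwas.induction import consolidate, parse_regex, render_regex

groups = [
    ["extensive bone metastasis", "extensive liver metastasis"],
    ["a reformed cigarette smoker", "a cigarette smoker"],
    ["SCC of the right tonsil -",
     "SCC of the right base of tongue -",
     "SCC of the right glossotonsillar sulcus -"],
]
for members in groups:
    rx = consolidate([tuple(m.split()) for m in members])
    print("members:", "; ".join(members))
    print("induced:", render_regex(rx))
    print()

rx = parse_regex("irradiation (and|with) (or without|concurrent) chemotherapy")
print("parsed elements:", len(rx.elements), "->", render_regex(rx))
print("\n'(a|b)' matches either token sequence; '(x)?' marks an optional run.")
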