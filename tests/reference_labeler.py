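"""Brute-force reference implementation of the fixation-categorization rules.

Deliberately naive and independent of the package implementation: pure
Python, explicit pairwise distance enumeration, no vectorization.  Used as
the oracle the production labeler must agree with exactly.
"""

import math


def reference_labels(x, y, radius=2.0, drop_pre_refixation=True):
    """Categorize one trial's fixations; returns a list of category strings."""
    n = len(x)

    def dist(i, j):
        return math.hypot(x[i] - x[j], y[i] - y[j])

    # step 1: which fixations qualify as a return, and to which first visit
    qualifies = [False] * n
    link = [None] * n
    for j in range(n):
        if j > 0 and dist(j, j - 1) < radius:
            continue  # arrived without leaving the previous spot
        for i in range(j - 1):
            within = dist(i, j) < radius
            left_region = any(dist(i, m) >= radius for m in range(i + 1, j))
            if within and left_region:
                qualifies[j] = True
                link[j] = i
                break
    # step 2: chains of consecutive returns keep only their first member
    refix = [qualifies[j] and not (j > 0 and qualifies[j - 1])
             for j in range(n)]
    # step 3: a fixation cannot be both precursor and refixation
    targets = {link[j] for j in range(n) if refix[j]}
    refix = [refix[j] and j not in targets for j in range(n)]
    precursors = {link[j] for j in range(n)
                  if refix[j] and not qualifies[link[j]]}

    pre_other = set()
    if drop_pre_refixation:
        for j in range(n):
            k = j - 1
            if refix[j] and k >= 0 and k not in precursors and not refix[k]:
                pre_other.add(k)

    cats = []
    for j in range(n):
        if refix[j]:
            cats.append("refixation")
        elif j in precursors:
            cats.append("precursor")
        elif j in pre_other:
            cats.append("other")
        elif all(dist(i, j) >= radius for i in range(n) if i != j):
            cats.append("ordinary")
        else:
            cats.append("other")
    return cats
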