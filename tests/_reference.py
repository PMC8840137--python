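"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: rows are plain lists
of dicts, entropy is a Counter loop, and the recursive rule generation
follows the procedural description step by step (explicit frequency
loops, strict-inequality majority, ascending stable sort on the score,
first-occurrence partition order).  Trees are returned as plain nested
dicts for node-for-node comparison.
"""

import math
from collections import Counter


def ref_entropy(values):
    """Brute-force -sum p log2 p over distinct tokens.

    fsum keeps the result independent of summation order, so scores that
    are mathematically tied compare exactly equal.
    """
    n = len(values)
    terms = []
    for _, f in Counter(values).items():
        fp = f / n
        terms.append(fp * math.log2(fp))
    return -math.fsum(terms)


def _ref_majority(rows, target):
    """Majority target value, first-encountered value kept on ties."""
    tav = []
    for r in rows:
        if r[target] not in tav:
            tav.append(r[target])
    highest_count = 0
    highest = ""
    for i, v in enumerate(tav):
        f = sum(1 for r in rows if r[target] == v)
        if i == 0 or highest_count < f:
            highest_count = f
            highest = v
    return highest


def ref_rule_generation(oa, rows, target):
    """Literal recursive rule generation; returns nested plain dicts."""
    tav = []
    for r in rows:
        if r[target] not in tav:
            tav.append(r[target])
    if len(oa) == 0:
        return {"leaf": True, "attribute": target,
                "class_value": _ref_majority(rows, target)}
    if len(tav) == 1:
        return {"leaf": True, "attribute": target, "class_value": tav[0]}
    # global disorder of the current rows' target values
    gda = ref_entropy([r[target] for r in rows])
    scores = []
    for attr in oa:
        lda = ref_entropy([r[attr] for r in rows])
        scores.append((attr, gda - lda))
    # ascending stable sort on score; minimum wins, earliest attr on ties
    scores_sorted = sorted(scores, key=lambda t: t[1])
    hpa = scores_sorted[0][0]
    new_oa = [a for a in oa if a != hpa]
    # partition in first-occurrence order of the HPA values
    values = []
    for r in rows:
        if r[hpa] not in values:
            values.append(r[hpa])
    branch_values, children = [], []
    for val in values:
        part = [r for r in rows if r[hpa] == val]
        branch_values.append(val)
        children.append(ref_rule_generation(new_oa, part, target))
    return {"leaf": False, "attribute": hpa,
            "branch_values": branch_values, "children": children}


def trees_equal(ref, node):
    """Compare a reference dict-tree with a package RuleNode."""
    if ref["leaf"]:
        return node.is_leaf and node.class_value == ref["class_value"]
    if node.is_leaf or node.attribute != ref["attribute"]:
        return False
    if list(node.branch_values) != [str(v) for v in ref["branch_values"]]:
        return False
    return all(trees_equal(r, c) for r, c in zip(ref["children"], node.children))
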