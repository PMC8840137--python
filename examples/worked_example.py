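"""Trace the rule learner by hand on the fixed 8-trial table.

Prints the global disorder amount of the target, each attribute's local
disorder and score, the chosen split, and the induced rule tree.  The
same numbers are derived step by step in docs/methods.md.
"""

from medivote import (attribute_scores, disorder_amount, generate_rules,
                      render_rules, worked_example_table)

table = worked_example_table()
print(f"{table.n_rows} trials, attributes {table.attributes}, "
      f"target {table.target!r}\n")

gda = disorder_amount(table.column("state"))
print(f"global disorder amount (target entropy): {gda:.6f} bits")

scores = attribute_scores(table)
for attr, lda, score in scores.per_attribute:
    print(f"  {attr:8s} local disorder {lda:.6f}  score {score:+.6f}")
print("both attributes tie at score 0; the first column wins the tie\n")

tree = generate_rules(table)
print(render_rules(tree))
print("The tree reads: high motion while lying is a fall; anything else "
      "is an activity of daily living.")
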