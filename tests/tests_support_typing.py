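"""Independent brute-force predicate oracle for the nine-type rules.

Kept separate from the implementation on purpose: this re-states the
rule table directly as nine predicates and reports every one that fires.
"""


def brute_force(vb, cb, vg, cg, thr=1.0):
    preds = {
        "A": vb <= thr and vg <= thr,
        "B": vb > thr and cb < 0 and vg <= thr,
        "C": vb > thr and cb > 0 and vg <= thr,
        "D": vb > thr and cb < 0 and vg > thr and cg > 0,
        "E": vb <= thr and vg > thr and cg > 0,
        "F": vb <= thr and vg > thr and cg < 0,
        "G": vb > thr and cb > 0 and vg > thr and cg < 0,
        "H": vb > thr and cb > 0 and vg > thr and cg > 0,
        "I": vb > thr and cb < 0 and vg > thr and cg < 0,
    }
    return [label for label, fired in preds.items() if fired]
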