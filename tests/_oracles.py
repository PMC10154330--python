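"""Brute-force counting oracles for the sequence descriptor families,
kept independent of the vectorized implementations they check."""

import itertools

from pepsl.descriptors import CONJOINT_CLASSES, CTD_GROUPS, _NORM_SCALES


def ctd_brute(seq):
    """Direct per-letter counting of CTD composition and transitions."""
    out = {}
    L = len(seq)
    for prop, groups in CTD_GROUPS.items():
        member = {a: gi for gi, g in enumerate(groups, 1) for a in g}
        for gi in (1, 2, 3):
            out[f"CTDC.{prop}.G{gi}"] = sum(
                1 for a in seq if member[a] == gi) / L
        for x, y in ((1, 2), (1, 3), (2, 3)):
            c = sum(
                1 for a, b in zip(seq, seq[1:])
                if {member[a], member[b]} == {x, y}
            )
            out[f"CTDT.{prop}.G{x}{y}"] = c / (L - 1)
    return out


def triad_brute(seq):
    member = {a: ci for ci, cls in enumerate(CONJOINT_CLASSES, 1) for a in cls}
    out = {}
    for i, j, k in itertools.product(range(1, 8), repeat=3):
        out[f"CT.{i}{j}{k}"] = float(sum(
            1 for t in range(len(seq) - 2)
            if (member[seq[t]], member[seq[t + 1]],
                member[seq[t + 2]]) == (i, j, k)
        ))
    return out


def autocorr_brute(seq, lag):
    out = {}
    L = len(seq)
    for sname, scale in _NORM_SCALES.items():
        p = [scale[a] for a in seq]
        pbar = sum(p) / L
        ss = sum((v - pbar) ** 2 for v in p)
        for d in range(1, lag + 1):
            nd = L - d
            out[f"MoreauBroto.{sname}.lag{d}"] = sum(
                p[i] * p[i + d] for i in range(nd)) / nd
            num = sum((p[i] - pbar) * (p[i + d] - pbar)
                      for i in range(nd)) / nd
            out[f"Moran.{sname}.lag{d}"] = num / (ss / L) if ss else 0.0
            gnum = sum((p[i] - p[i + d]) ** 2 for i in range(nd)) / (2 * nd)
            out[f"Geary.{sname}.lag{d}"] = gnum / (ss / (L - 1)) if ss else 0.0
    return out
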