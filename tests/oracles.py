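"""Independent reference implementations used only by the tests.

These deliberately avoid the package's code paths: the Wald intervals and
the information-component closed form are re-evaluated with mpmath at 50
significant digits, and pair counting is a literal double loop.
"""

import mpmath as mp

mp.mp.dps = 50

Z = mp.mpf("1.959963984540054")


def prr_oracle(a, b, c, d):
    a, b, c, d = (mp.mpf(x) for x in (a, b, c, d))
    prr = (a / (a + b)) / (c / (c + d))
    se = mp.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return prr, prr * mp.e ** (-Z * se), prr * mp.e ** (Z * se)


def ror_oracle(a, b, c, d):
    a, b, c, d = (mp.mpf(x) for x in (a, b, c, d))
    ror = (a * d) / (b * c)
    se = mp.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * mp.e ** (-Z * se), ror * mp.e ** (Z * se)


def bcpnn_oracle(a, b, c, d, alpha1=1, beta1=1, alpha=2, beta=2, gamma11=1):
    a, b, c, d = (mp.mpf(x) for x in (a, b, c, d))
    alpha1, beta1, alpha, beta, gamma11 = (
        mp.mpf(x) for x in (alpha1, beta1, alpha, beta, gamma11)
    )
    C = a + b + c + d
    Cx = a + b
    Cy = a + c
    Cxy = a
    g = gamma11 * (C + alpha) * (C + beta) / ((Cx + alpha1) * (Cy + beta1))
    eic = mp.log(
        (Cxy + gamma11) * (C + alpha) * (C + beta) / ((C + g) * (Cx + alpha1) * (Cy + beta1)),
        2,
    )
    vic = (
        (C - Cxy + g - gamma11) / ((Cxy + gamma11) * (1 + C + g))
        + (C - Cx + alpha - alpha1) / ((Cx + alpha1) * (1 + C + alpha))
        + (C - Cy + beta - beta1) / ((Cy + beta1) * (1 + C + beta))
    ) / mp.log(2) ** 2
    return eic, vic, eic - 2 * mp.sqrt(vic)


def brute_force_tables(exposed, background):
    """Literal double loop over reports x PT vocabulary."""
    vocab = set()
    for rec in exposed:
        vocab |= rec.reactions
    tables = {}
    exp_pairs = [(r.case_id, pt) for r in exposed for pt in sorted(r.reactions)]
    bg_pairs = [(r.case_id, pt) for r in background for pt in sorted(r.reactions)]
    for pt in vocab:
        a = sum(1 for _, p in exp_pairs if p == pt)
        c = sum(1 for _, p in bg_pairs if p == pt)
        tables[pt] = (a, len(exp_pairs) - a, c, len(bg_pairs) - c)
    return tables
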