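"""Independent brute-force reimplementations of the four stability
algorithms, written with explicit Python loops and the ``statistics``
module so they share no code path with the package. Used as oracles."""

import math
import statistics


def _log2_quantities(matrix):
    qs = []
    for gi, g in enumerate(matrix.genes):
        e = matrix.efficiency[g]
        row = list(matrix.ct[gi])
        m = min(row)
        qs.append([(m - ct) * math.log2(e) for ct in row])
    return qs


def brute_genorm_m(matrix):
    """M_g = mean over partners of stdev of pairwise log2 ratios."""
    y = _log2_quantities(matrix)
    G = len(y)
    out = {}
    for g in range(G):
        sds = []
        for h in range(G):
            if h == g:
                continue
            ratios = [y[g][s] - y[h][s] for s in range(len(y[g]))]
            sds.append(statistics.stdev(ratios))
        out[matrix.genes[g]] = sum(sds) / len(sds)
    return out


def brute_genorm_exclusion(matrix):
    """Worst-first exclusion order by repeated brute-force M recomputation."""
    remaining = list(matrix.genes)
    order = []
    while len(remaining) > 2:
        m = brute_genorm_m(matrix.subset(genes=remaining))
        worst = max(remaining, key=lambda g: (m[g], g))
        order.append(worst)
        remaining.remove(worst)
    return order, tuple(remaining)


def brute_delta_ct(matrix):
    G = len(matrix.genes)
    out = {}
    for g in range(G):
        sds = []
        for h in range(G):
            if h == g:
                continue
            diffs = [matrix.ct[g][s] - matrix.ct[h][s] for s in range(matrix.n_samples)]
            sds.append(statistics.stdev(diffs))
        out[matrix.genes[g]] = sum(sds) / len(sds)
    return out


def brute_normfinder(matrix):
    """Ungrouped model-based stability by direct formula evaluation."""
    y = _log2_quantities(matrix)
    G, n = len(y), len(y[0])
    grand = sum(sum(row) for row in y) / (G * n)
    gmeans = [sum(row) / n for row in y]
    smeans = [sum(y[g][s] for g in range(G)) / G for s in range(n)]
    s2 = []
    for g in range(G):
        resid = [y[g][s] - gmeans[g] - smeans[s] + grand for s in range(n)]
        s2.append(sum(r * r for r in resid) / (n - 1))
    total = G / (G - 1) * sum(s2)
    out = {}
    for g in range(G):
        var = G / (G - 2) * (s2[g] - total / G**2)
        out[matrix.genes[g]] = math.sqrt(max(0.0, var))
    return out


def brute_bestkeeper(matrix, dialect="mad"):
    out = {}
    for g in range(len(matrix.genes)):
        row = list(matrix.ct[g])
        mean = sum(row) / len(row)
        if dialect == "mad":
            out[matrix.genes[g]] = sum(abs(x - mean) for x in row) / len(row)
        else:
            out[matrix.genes[g]] = statistics.stdev(row)
    return out


def brute_bestkeeper_index(matrix):
    """Per-sample geometric mean of Ct across genes."""
    return [
        math.exp(
            sum(math.log(matrix.ct[g][s]) for g in range(len(matrix.genes)))
            / len(matrix.genes)
        )
        for s in range(matrix.n_samples)
    ]


BRUTE = {
    "delta_ct": brute_delta_ct,
    "bestkeeper": brute_bestkeeper,
    "normfinder": brute_normfinder,
    "genorm": brute_genorm_m,
}
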