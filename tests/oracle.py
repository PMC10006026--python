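"""Independent brute-force oracle for the stability indices.

Everything here is computed with plain Python loops straight from the
defining sums, sharing no code with the package: lists of lists in, dicts
of per-genotype values out.  Used to cross-check the vectorized
implementations on small tables.
"""

from math import erf, log10, sqrt


def _genotype_means(x):
    return [sum(row) / len(row) for row in x]


def _env_means(x):
    g, e = len(x), len(x[0])
    return [sum(x[i][j] for i in range(g)) / g for j in range(e)]


def _grand_mean(x):
    return sum(sum(row) for row in x) / (len(x) * len(x[0]))


def _env_index(x):
    gm = _grand_mean(x)
    return [m - gm for m in _env_means(x)]


def environmental_variance(x):
    out = {}
    for i, row in enumerate(x):
        m = sum(row) / len(row)
        out[i] = sum((v - m) ** 2 for v in row) / (len(row) - 1)
    return out


def adjusted_cv(x):
    """Taylor-power-law-adjusted CV (%), via the defining log10 algebra."""
    means = _genotype_means(x)
    var = environmental_variance(x)
    ms = [log10(means[i]) for i in range(len(x))]
    vs = [log10(var[i]) for i in range(len(x))]
    n = len(ms)
    mbar = sum(ms) / n
    vbar = sum(vs) / n
    sxx = sum((m - mbar) ** 2 for m in ms)
    sxy = sum((ms[i] - mbar) * (vs[i] - vbar) for i in range(n))
    b = sxy / sxx
    out = {}
    for i in range(n):
        v_adj = vs[i] + (2.0 - b) * (ms[i] - mbar)
        out[i] = 100.0 * 10.0 ** (v_adj / 2.0 - ms[i])
    return out


def coefficient_of_regression(x):
    ij = _env_index(x)
    ss = sum(v * v for v in ij)
    out = {}
    for i, row in enumerate(x):
        m = sum(row) / len(row)
        out[i] = sum((row[j] - m) * ij[j] for j in range(len(row))) / ss
    return out


def coefficient_of_determination(x):
    b = coefficient_of_regression(x)
    ij = _env_index(x)
    ss_env = sum(v * v for v in ij)
    out = {}
    for i, row in enumerate(x):
        m = sum(row) / len(row)
        ss_tot = sum((v - m) ** 2 for v in row)
        out[i] = b[i] ** 2 * ss_env / ss_tot
    return out


def deviation_mean_squares(x):
    b = coefficient_of_regression(x)
    ij = _env_index(x)
    out = {}
    for i, row in enumerate(x):
        m = sum(row) / len(row)
        ss = sum((row[j] - m - b[i] * ij[j]) ** 2 for j in range(len(row)))
        out[i] = ss / (len(row) - 2)
    return out


def ecovalence(x, modified=False):
    em = _env_means(x)
    gm = _grand_mean(x)
    out = {}
    for i, row in enumerate(x):
        m = sum(row) / len(row)
        w = sum((row[j] - m - em[j] + gm) ** 2 for j in range(len(row)))
        out[i] = w / len(row) if modified else w
    return out


def genotypic_stability(x):
    b = coefficient_of_regression(x)
    b_min = min(b.values())
    ij = _env_index(x)
    out = {}
    for i, row in enumerate(x):
        m = sum(row) / len(row)
        out[i] = sum((row[j] - m - b_min * ij[j]) ** 2 for j in range(len(row)))
    return out


def superiority_measure(x):
    g, e = len(x), len(x[0])
    maxima = [max(x[i][j] for i in range(g)) for j in range(e)]
    return {
        i: sum((x[i][j] - maxima[j]) ** 2 for j in range(e)) / (2 * e)
        for i in range(g)
    }


def _norm_cdf(z):
    return 0.5 * (1.0 + erf(z / sqrt(2.0)))


def safety_first_index(x, lam):
    out = {}
    for i, row in enumerate(x):
        m = sum(row) / len(row)
        sd = sqrt(sum((v - m) ** 2 for v in row) / (len(row) - 1))
        out[i] = _norm_cdf((lam - m) / sd)
    return out


def stability_variance(x):
    """Shukla's variance from the two-way ANOVA interaction residuals."""
    g, e = len(x), len(x[0])
    em = _env_means(x)
    gm = _grand_mean(x)
    w = {}
    for i, row in enumerate(x):
        m = sum(row) / len(row)
        w[i] = sum((row[j] - m - em[j] + gm) ** 2 for j in range(e))
    w_sum = sum(w.values())
    return {
        i: g * w[i] / ((g - 2) * (e - 1))
        - w_sum / ((g - 1) * (g - 2) * (e - 1))
        for i in range(g)
    }


def _ranks_with_ties(values):
    """Ascending ranks; tied values share the average rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def variance_of_rank(x):
    g, e = len(x), len(x[0])
    gm = _grand_mean(x)
    means = _genotype_means(x)
    corrected = [[x[i][j] - means[i] + gm for j in range(e)] for i in range(g)]
    ranks = [[0.0] * e for _ in range(g)]
    for j in range(e):
        col = _ranks_with_ties([corrected[i][j] for i in range(g)])
        for i in range(g):
            ranks[i][j] = col[i]
    out = {}
    for i in range(g):
        rbar = sum(ranks[i]) / e
        out[i] = sum((r - rbar) ** 2 for r in ranks[i]) / (e - 1)
    return out


ORACLES = {
    "environmental_variance": environmental_variance,
    "adjusted_cv": adjusted_cv,
    "coefficient_of_regression": coefficient_of_regression,
    "coefficient_of_determination": coefficient_of_determination,
    "deviation_mean_squares": deviation_mean_squares,
    "ecovalence": ecovalence,
    "ecovalence_modified": lambda x: ecovalence(x, modified=True),
    "genotypic_stability": genotypic_stability,
    "superiority_measure": superiority_measure,
    "stability_variance": stability_variance,
    "variance_of_rank": variance_of_rank,
}
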