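"""Independent step-by-step PLS path-modelling oracle.

A deliberately plain reference implementation, written with explicit
Python loops and its own Gaussian elimination, used only to cross-check
the vectorised engine.  It follows the textbook algorithm directly:
standardize, initialise unit weights, alternate outer/inner steps under
the path weighting scheme (Mode A = covariance with the proxy, Mode B =
regression of the proxy on the block), then read off loadings and OLS
path coefficients and orient each construct to a positive loading sum.
"""

import math


def mean(xs):
    return sum(xs) / len(xs)


def sd(xs):
    m = mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def standardize_col(xs):
    m, s = mean(xs), sd(xs)
    return [(x - m) / s for x in xs]


def dot(a, b):
    return sum(x * y for x, y in zip(a, b))


def cov1(a, b):
    # covariance with n-1 denominator for centred unit-variance columns
    return dot(a, b) / (len(a) - 1)


def gauss_solve(A, b):
    """Solve A x = b by Gaussian elimination with partial pivoting."""
    n = len(b)
    M = [row[:] + [b[i]] for i, row in enumerate(A)]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(M[r][col]))
        M[col], M[piv] = M[piv], M[col]
        for r in range(col + 1, n):
            f = M[r][col] / M[col][col]
            for c in range(col, n + 1):
                M[r][c] -= f * M[col][c]
    x = [0.0] * n
    for r in range(n - 1, -1, -1):
        x[r] = (M[r][n] - sum(M[r][c] * x[c] for c in range(r + 1, n))) / M[r][r]
    return x


def pls_oracle(columns, blocks, paths, tol=1e-10, max_iter=500):
    """Estimate a PLS path model.

    columns : dict name -> list of raw values
    blocks  : list of (construct_name, mode, [indicator names]), mode in
              {"reflective", "formative"}
    paths   : list of (source_construct, target_construct)

    Returns dict with "weights", "loadings" (dict per indicator),
    "paths" (dict per (source, target)), "scores" (dict per construct),
    "r2" (dict per endogenous construct).
    """
    X = {name: standardize_col(vals) for name, vals in columns.items()}
    n = len(next(iter(X.values())))
    names = [b[0] for b in blocks]
    mode = {b[0]: b[1] for b in blocks}
    inds = {b[0]: list(b[2]) for b in blocks}
    preds = {c: [s for s, t in paths if t == c] for c in names}
    succs = {c: [t for s, t in paths if s == c] for c in names}

    def composite(c, w):
        y = [sum(w[k] * X[x][i] for k, x in enumerate(inds[c])) for i in range(n)]
        s = sd(y)
        return [v / s for v in y], [v / s for v in w]

    weights, scores = {}, {}
    for c in names:
        scores[c], weights[c] = composite(c, [1.0] * len(inds[c]))

    for _ in range(max_iter):
        # inner proxies, path scheme
        proxies = {}
        for c in names:
            z = [0.0] * n
            if preds[c]:
                P = preds[c]
                A = [[cov1(scores[p], scores[q]) for q in P] for p in P]
                b = [cov1(scores[p], scores[c]) for p in P]
                coef = gauss_solve(A, b)
                for k, p in enumerate(P):
                    for i in range(n):
                        z[i] += coef[k] * scores[p][i]
            for t in succs[c]:
                r = cov1(scores[c], scores[t])
                for i in range(n):
                    z[i] += r * scores[t][i]
            proxies[c] = z
        # outer update
        delta = 0.0
        for c in names:
            if not preds[c] and not succs[c]:
                continue
            if mode[c] == "formative":
                A = [
                    [cov1(X[a], X[b_]) for b_ in inds[c]]
                    for a in inds[c]
                ]
                b = [cov1(X[x], proxies[c]) for x in inds[c]]
                w_new = gauss_solve(A, b)
            else:
                w_new = [cov1(X[x], proxies[c]) for x in inds[c]]
            y_new, w_new = composite(c, w_new)
            delta = max(delta, max(abs(a - b) for a, b in zip(w_new, weights[c])))
            weights[c], scores[c] = w_new, y_new
        if delta < tol:
            break

    loadings = {
        x: cov1(X[x], scores[c]) for c in names for x in inds[c]
    }
    # orient: positive loading sum per construct
    for c in names:
        if sum(loadings[x] for x in inds[c]) < 0:
            weights[c] = [-w for w in weights[c]]
            scores[c] = [-v for v in scores[c]]
            for x in inds[c]:
                loadings[x] = -loadings[x]
    path_coefs, r2 = {}, {}
    for c in names:
        if not preds[c]:
            continue
        P = preds[c]
        A = [[cov1(scores[p], scores[q]) for q in P] for p in P]
        b = [cov1(scores[p], scores[c]) for p in P]
        coef = gauss_solve(A, b)
        for k, p in enumerate(P):
            path_coefs[(p, c)] = coef[k]
        r2[c] = sum(coef[k] * b[k] for k in range(len(P)))
    return {
        "weights": {x: weights[c][k] for c in names for k, x in enumerate(inds[c])},
        "loadings": loadings,
        "paths": path_coefs,
        "scores": scores,
        "r2": r2,
    }
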