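"""Independent brute-force oracles used to validate the vectorized code paths.

Everything here is written as literal scalar loops (math module, fsum), with
no shared code with the package, so agreement is a genuine cross-check.
"""

import math


def acf_bruteforce(y, max_lag):
    """Double-loop biased autocorrelation with a single global mean."""
    T = len(y)
    ybar = math.fsum(y) / T
    c = []
    for k in range(max_lag + 1):
        terms = [(y[t] - ybar) * (y[t + k] - ybar) for t in range(T - k)]
        c.append(math.fsum(terms) / T)
    return [ck / c[0] for ck in c]


def lstm_step_bruteforce(W_i, W_f, W_o, W_c, U_i, U_f, U_o, U_c,
                         b_i, b_f, b_o, b_c, x, h_prev, c_prev):
    """Literal per-component gated-cell step: returns (h, c, gates)."""

    def sig(z):
        return 1.0 / (1.0 + math.exp(-z))

    H = len(b_i)
    D = len(x)
    h_new, c_new = [], []
    gates = []
    for j in range(H):
        zi = math.fsum([W_i[j][d] * x[d] for d in range(D)]
                       + [U_i[j][k] * h_prev[k] for k in range(H)]) + b_i[j]
        zf = math.fsum([W_f[j][d] * x[d] for d in range(D)]
                       + [U_f[j][k] * h_prev[k] for k in range(H)]) + b_f[j]
        zo = math.fsum([W_o[j][d] * x[d] for d in range(D)]
                       + [U_o[j][k] * h_prev[k] for k in range(H)]) + b_o[j]
        zc = math.fsum([W_c[j][d] * x[d] for d in range(D)]
                       + [U_c[j][k] * h_prev[k] for k in range(H)]) + b_c[j]
        i, f, o = sig(zi), sig(zf), sig(zo)
        g = math.tanh(zc)
        c = f * c_prev[j] + i * g
        h = o * math.tanh(c)
        c_new.append(c)
        h_new.append(h)
        gates.append((i, f, o, g))
    return h_new, c_new, gates


def rmse_bruteforce(O, P):
    n = len(O)
    return math.sqrt(math.fsum((O[i] - P[i]) ** 2 for i in range(n)) / n)


def nmse_bruteforce(O, P):
    n = len(O)
    mse = math.fsum((P[i] - O[i]) ** 2 for i in range(n)) / n
    return mse / ((math.fsum(P) / n) * (math.fsum(O) / n))


def pearson_bruteforce(O, P):
    n = len(O)
    Obar = math.fsum(O) / n
    Pbar = math.fsum(P) / n
    num = math.fsum((O[i] - Obar) * (P[i] - Pbar) for i in range(n))
    dO = math.fsum((O[i] - Obar) ** 2 for i in range(n))
    dP = math.fsum((P[i] - Pbar) ** 2 for i in range(n))
    return num / math.sqrt(dO * dP)


def count_valid_windows(missing_by_day, n_days, offsets):
    """Enumerate forecast days whose referenced days are all gap-free.

    ``missing_by_day[d]`` is True when day d contains any missing value in a
    referenced channel; ``offsets`` are the day offsets (0 = forecast day).
    """
    count = 0
    for d in range(n_days):
        if all(0 <= d + o < n_days and not missing_by_day[d + o] for o in offsets):
            count += 1
    return count
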