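"""Independent oracles used by the test suite.

The equation oracles below are a second, literal transcription of the nine
published formulas, written as plain arithmetic expressions with no shared
code with the package registry — they exist so the registry's declarative
encoding can be checked against an independent reading of the same formulas.

The Bland-Altman oracle is a brute-force pure-Python loop (no numpy), used to
check the vectorised implementation to near machine precision.
"""

import math
import statistics


# --- literal equation transcriptions -------------------------------------

def chumlea(sex, mac, cc, sst, kh):
    if sex == "female":
        return (mac * 0.98) + (cc * 1.27) + (sst * 0.40) + (kh * 0.87) - 62.35
    return (mac * 1.73) + (cc * 0.98) + (sst * 0.37) + (kh * 1.16) - 81.69


def rabito1(mac, ac, cc, sst):
    return (0.5030 * mac) + (0.5632 * ac) + (1.3180 * cc) + (0.0339 * sst) - 43.1560


def rabito2(mac, ac, cc):
    return (0.4808 * mac) + (0.5646 * ac) + (1.316 * cc) - 42.2450


def rabito3(mac, ac, cc, sex):
    s = 1 if sex == "male" else 2
    return (0.5759 * mac) + (0.5263 * ac) + (1.2452 * cc) - (4.8689 * s) - 32.9241


def crandall(sex, mac, height):
    if sex == "female":
        return -64.6 + (2.15 * mac) + (0.54 * height)
    return -93.2 + (3.29 * mac) + (0.43 * height)


def lorenz(sex, height, ac, hc):
    if sex == "male":
        return -137.432 + (0.60035 * height) + (0.785 * ac) + (0.392 * hc)
    return -110.924 + (0.4053 * height) + (0.325 * ac) + (0.836 * hc)


def kokong(height):
    return height - 100


def jung(sex, kh, mac, age):
    if sex == "male":
        return kh * 0.928 + mac * 2.508 - age * 0.144 - 42.543
    return kh * 0.826 + mac * 2.116 - age * 0.133 - 31.486


def cattermole(mac):
    return (4 * mac) - 50


def oracle_predict(equation_id, sex, **m):
    """Dispatch to the literal transcription by registry id."""
    return {
        "Ch": lambda: chumlea(sex, m["mac"], m["cc"], m["sst"], m["kh"]),
        "R1": lambda: rabito1(m["mac"], m["ac"], m["cc"], m["sst"]),
        "R2": lambda: rabito2(m["mac"], m["ac"], m["cc"]),
        "R3": lambda: rabito3(m["mac"], m["ac"], m["cc"], sex),
        "Cr": lambda: crandall(sex, m["mac"], m["height"]),
        "L": lambda: lorenz(sex, m["height"], m["ac"], m["hc"]),
        "KK": lambda: kokong(m["height"]),
        "J": lambda: jung(sex, m["kh"], m["mac"], m["age"]),
        "C": lambda: cattermole(m["mac"]),
    }[equation_id]()


# --- brute-force accuracy statistics --------------------------------------

def loop_p_within(predicted, actual, tol):
    hits = 0
    for p, a in zip(predicted, actual):
        if abs(p - a) / a <= tol:
            hits += 1
    return 100.0 * hits / len(actual)


def loop_mpe(predicted, actual):
    errs = [100.0 * (p - a) / a for p, a in zip(predicted, actual)]
    return sum(errs) / len(errs)


def loop_bland_altman(predicted, actual):
    """Brute-force bias/SD/LOA and 95% CIs; returns a plain dict."""
    from scipy.stats import t as t_dist

    d = [p - a for p, a in zip(predicted, actual)]
    n = len(d)
    bias = sum(d) / n
    sd = math.sqrt(sum((x - bias) ** 2 for x in d) / (n - 1))
    lo = bias - 1.96 * sd
    hi = bias + 1.96 * sd
    tc = float(t_dist.ppf(0.975, n - 1))
    se_b = sd / math.sqrt(n)
    se_l = sd * math.sqrt(3.0 / n)
    return {
        "bias": bias, "sd": sd, "loa_lower": lo, "loa_upper": hi,
        "bias_ci": (bias - tc * se_b, bias + tc * se_b),
        "loa_lower_ci": (lo - tc * se_l, lo + tc * se_l),
        "loa_upper_ci": (hi - tc * se_l, hi + tc * se_l),
    }
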