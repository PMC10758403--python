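"""Independent brute-force reference implementations.

These deliberately share no code with :mod:`cpcub`: plain dict/loop
arithmetic straight from the defining formulas, used to freeze expected
values and to check oracle equivalence on random inputs.
"""

from __future__ import annotations

import math

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]


def families_11() -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in _TABLE.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return fams


def rscu_brute(counts: dict[str, int]) -> dict[str, float]:
    out = {}
    for aa, fam in families_11().items():
        total = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            if total == 0:
                out[c] = math.nan
            elif len(fam) == 1:
                out[c] = 1.0
            else:
                out[c] = counts.get(c, 0) * len(fam) / total
    return out


def enc_brute(counts: dict[str, int]) -> float:
    """Wright's estimator, no fallbacks: requires every family size to
    have at least one family with n >= 2 and positive mean F."""
    f_by_size: dict[int, list[float]] = {}
    n_families_by_size: dict[int, int] = {}
    n_singletons = 0
    for aa, fam in families_11().items():
        k = len(fam)
        if k == 1:
            n_singletons += 1
            continue
        n_families_by_size[k] = n_families_by_size.get(k, 0) + 1
        n = sum(counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        s = sum((counts.get(c, 0) / n) ** 2 for c in fam)
        f_by_size.setdefault(k, []).append((n * s - 1) / (n - 1))
    enc = float(n_singletons)
    for k, n_fam in n_families_by_size.items():
        fs = f_by_size.get(k, [])
        mean_f = sum(fs) / len(fs) if fs else 0.0
        if mean_f <= 0:
            return math.nan
        enc += n_fam / mean_f
    return min(max(enc, 20.0), 61.0)


def cai_brute(counts: dict[str, int], ref_rscu: dict[str, float], w_floor=0.01) -> float:
    fams = families_11()
    w = {}
    for aa, fam in fams.items():
        defined = [ref_rscu[c] for c in fam if not math.isnan(ref_rscu.get(c, math.nan))]
        if not defined or max(defined) <= 0:
            continue
        for c in fam:
            if not math.isnan(ref_rscu.get(c, math.nan)):
                w[c] = ref_rscu[c] / max(defined)
    log_sum, n = 0.0, 0
    for aa, fam in fams.items():
        if len(fam) == 1:
            continue
        for c in fam:
            k = counts.get(c, 0)
            if k:
                log_sum += k * math.log(max(w[c], w_floor))
                n += k
    return math.exp(log_sum / n)


def fpkm_brute(counts, lengths, libs):
    """counts: dict gene -> dict sample -> int."""
    out = {}
    for g, row in counts.items():
        out[g] = {
            s: c * 1e9 / (libs[s] * lengths[g]) for s, c in row.items()
        }
    return out
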