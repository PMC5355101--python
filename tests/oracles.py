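"""Naive reference implementations used as independent oracles in tests.

Everything here is written as plain double loops over symbol strings and
dictionary lookups — O(L * lambda * Lambda) with no vectorization — so it
shares no code path with the package's numpy implementation.
"""

import numpy as np

from psekit.pseudo_components import unit_alphabet


def _units(seq, index):
    if index.unit == "residue":
        return [seq.residues[i] for i in range(seq.L)]
    return [seq.residues[i : i + 2] for i in range(seq.L - 1)]


def _value(index, name, symbol):
    symbols = unit_alphabet(index.molecule, index.unit)
    return index.matrix[index.names.index(name), symbols.index(symbol)]


def oracle_theta(seq, index, lam):
    units = _units(seq, index)
    out = []
    for j in range(1, lam + 1):
        total = 0.0
        n_terms = len(units) - j
        for i in range(n_terms):
            big_theta = 0.0
            for name in index.names:
                d = _value(index, name, units[i]) - _value(index, name, units[i + j])
                big_theta += d * d
            total += big_theta / len(index.names)
        out.append(total / n_terms)
    return np.array(out)


def oracle_tau(seq, index, lam):
    units = _units(seq, index)
    out = []
    for j in range(1, lam + 1):
        n_terms = len(units) - j
        for name in index.names:
            total = 0.0
            for i in range(n_terms):
                total += _value(index, name, units[i]) * _value(
                    index, name, units[i + j]
                )
            out.append(total / n_terms)
    return np.array(out)


def oracle_kmer_composition(seq, k, alphabet):
    import itertools

    kmers = ["".join(p) for p in itertools.product(alphabet, repeat=k)]
    windows = [seq.residues[i : i + k] for i in range(seq.L - k + 1)]
    return np.array([windows.count(m) / len(windows) for m in kmers])


def oracle_pse_vector(seq, params, index, alphabet):
    f = oracle_kmer_composition(seq, params.k, alphabet)
    if params.mode == "parallel":
        corr = oracle_theta(seq, index, params.lam)
    else:
        corr = oracle_tau(seq, index, params.lam)
    denom = 1.0 + params.w * corr.sum()
    return np.concatenate([f, params.w * corr]) / denom
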