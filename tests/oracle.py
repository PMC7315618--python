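"""Independent brute-force in-silico PCR enumerator used as a test oracle.

Deliberately written from scratch against the matching rules (degenerate
base-set intersection, per-primer mismatch budget, 3'-terminal criterion,
convergent orientation, length cap) without reusing any engine code: the
minus strand is handled by reverse-complementing each *window* and
comparing the primer to it directly, whereas the engine compares a
reverse-complemented primer to the forward-strand window.
"""

from itertools import product as iproduct

ORACLE_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_ORACLE_COMP = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def oracle_revcomp(seq):
    return "".join(_ORACLE_COMP[c] for c in reversed(seq))


def oracle_compatible(a, b):
    return len(ORACLE_SETS[a] & ORACLE_SETS[b]) > 0


def oracle_sites(primer_seq, seq, max_mm):
    """All (strand, start, end, mismatches, three_prime) windows within budget."""
    m = len(primer_seq)
    out = []
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        mm = sum(1 for p, t in zip(primer_seq, window) if not oracle_compatible(p, t))
        if mm <= max_mm:
            out.append(("+", i, i + m, mm, oracle_compatible(primer_seq[-1], window[-1])))
        window_rc = oracle_revcomp(window)
        mm = sum(1 for p, t in zip(primer_seq, window_rc) if not oracle_compatible(p, t))
        if mm <= max_mm:
            out.append(("-", i, i + m, mm, oracle_compatible(primer_seq[-1], window_rc[-1])))
    return out


def oracle_amplify(fwd_seq, rev_seq, seq, max_mm, require3, max_len):
    """All convergent products as (fwd_start, rev_end_or_span, strand, product)."""
    fsites = oracle_sites(fwd_seq, seq, max_mm)
    rsites = oracle_sites(rev_seq, seq, max_mm)
    products = set()
    for f, r in iproduct(fsites, rsites):
        fstrand, fs, fe, _, f3 = f
        rstrand, rs, re_, _, r3 = r
        if require3 and not (f3 and r3):
            continue
        if fstrand == "+" and rstrand == "-" and rs >= fe:
            length = re_ - fs
            if length <= max_len:
                products.add((fs, re_, "+", seq[fs:re_]))
        elif fstrand == "-" and rstrand == "+" and fs >= re_:
            length = fe - rs
            if length <= max_len:
                products.add((rs, fe, "-", oracle_revcomp(seq[rs:fe])))
    return products


def random_degenerate_seq(rng, max_len=400, degenerate_frac=0.10):
    """Random template: ACGT with ~10% degenerate codes."""
    n = int(rng.integers(60, max_len + 1))
    plain = rng.choice(list("ACGT"), size=n)
    degen = rng.choice(list("RYSWKMBDHVN"), size=n)
    use_degen = rng.random(n) < degenerate_frac
    return "".join(d if u else p for p, d, u in zip(plain, degen, use_degen))
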