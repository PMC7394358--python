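"""Shared helpers for building random and planted test instances."""

from __future__ import annotations

import numpy as np

from irscan import reverse_complement

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def random_instance(rng: np.random.Generator) -> tuple[str, str]:
    """A gene (<=1 kb) / window (<=2 kb) pair at GC 0.25-0.75 with 0-3
    planted reverse-complement segments (12-120 bp, so some below the 20-bp
    threshold), occasional low-complexity runs, and occasional Ns."""
    gc = rng.uniform(0.25, 0.75)
    glen = int(rng.integers(50, 1001))
    wlen = int(rng.integers(100, 2001))
    gene = list(rand_seq(rng, glen, gc))
    window = list(rand_seq(rng, wlen, gc))
    for _ in range(int(rng.integers(0, 4))):
        L = int(rng.integers(12, 121))
        if L > glen or L > wlen:
            continue
        a = int(rng.integers(0, glen - L + 1))
        p = int(rng.integers(0, wlen - L + 1))
        window[p : p + L] = reverse_complement("".join(gene[a : a + L]))
    if rng.random() < 0.15:  # low-complexity stress: shared homopolymer
        L = int(rng.integers(20, 60))
        if L <= glen and L <= wlen:
            a = int(rng.integers(0, glen - L + 1))
            p = int(rng.integers(0, wlen - L + 1))
            gene[a : a + L] = "A" * L
            window[p : p + L] = "T" * L
    if rng.random() < 0.2:
        for _ in range(int(rng.integers(1, 6))):
            window[int(rng.integers(0, wlen))] = "N"
    return "".join(gene), "".join(window)


def plant_exact(
    rng: np.random.Generator, gene: list[str], window: list[str], a: int, p: int, L: int
) -> None:
    """Plant reverse_complement(gene[a:a+L]) at window[p:p+L] in place, and
    force the flanking window bases to break any one-base extension so the
    planted maximal match has exactly the intended coordinates."""
    sub = "".join(gene[a : a + L])
    window[p : p + L] = reverse_complement(sub)
    if a + L < len(gene) and p > 0:
        bad = _COMP[gene[a + L]]
        if window[p - 1] == bad:
            window[p - 1] = "A" if bad != "A" else "C"
    if a > 0 and p + L < len(window):
        bad = _COMP[gene[a - 1]]
        if window[p + L] == bad:
            window[p + L] = "A" if bad != "A" else "C"


def hit_coords(hits) -> set[tuple]:
    return {
        (h.gene_start, h.gene_end, h.partner_start, h.partner_end, h.length)
        for h in hits
    }
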