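"""IUPAC consensus motif scanning and sequence-level enrichment.

Replaces de-novo discovery with known-motif analysis: scan peak
sequences for a degenerate consensus (e.g. NCGGAAMM), compare the
fraction of sequences carrying at least one hit against a background
(dinucleotide-shuffled foreground by default), and test enrichment with
a one-sided binomial test.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome import ValidationError

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


class IupacMotif:
    """A consensus motif over the IUPAC degenerate-nucleotide alphabet."""

    def __init__(self, consensus: str) -> None:
        consensus = consensus.upper()
        if not consensus:
            raise ValidationError("motif consensus must be non-empty")
        bad = set(consensus) - set(IUPAC)
        if bad:
            raise ValidationError(f"invalid IUPAC codes in consensus: {sorted(bad)}")
        self.consensus = consensus
        self._sets = [IUPAC[c] for c in consensus]
        self._rc = reverse_complement(consensus)
        self._rc_sets = [IUPAC[c] for c in self._rc]
        self._fwd_re = re.compile("(?=" + _to_regex(consensus) + ")")
        self._rev_re = re.compile("(?=" + _to_regex(self._rc) + ")")

    def __len__(self) -> int:
        return len(self.consensus)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"IupacMotif({self.consensus!r})"


def _to_regex(consensus: str) -> str:
    parts = []
    for code in consensus:
        if code == "N":
            parts.append(".")  # N matches anything, including ambiguous bases
        else:
            parts.append("[" + "".join(sorted(IUPAC[code])) + "]")
    return "".join(parts)


def match_at(motif: IupacMotif, sequence: str, position: int, strand: str = "+") -> bool:
    """Does the motif match at ``position`` (0-based, forward coordinates)?

    On the '-' strand the reverse complement of the motif is tested
    against the forward sequence. Sequence characters outside ACGT match
    only where the motif code is N.
    """
    if position < 0 or position + len(motif) > len(sequence):
        raise ValidationError("motif window exceeds sequence bounds")
    sets = motif._sets if strand == "+" else motif._rc_sets
    window = sequence[position : position + len(motif)].upper()
    for ch, allowed in zip(window, sets):
        if allowed == IUPAC["N"]:
            continue
        if ch not in allowed:
            return False
    return True


def scan(
    motif: IupacMotif, sequence: str, both_strands: bool = True
) -> list[tuple[int, str]]:
    """All (position, strand) hits; overlapping hits are all reported."""
    seq = sequence.upper()
    hits = [(m.start(), "+") for m in motif._fwd_re.finditer(seq)]
    if both_strands:
        hits.extend((m.start(), "-") for m in motif._rev_re.finditer(seq))
    hits.sort()
    return hits


def has_hit(motif: IupacMotif, sequence: str, both_strands: bool = True) -> bool:
    seq = sequence.upper()
    if motif._fwd_re.search(seq):
        return True
    return bool(both_strands and motif._rev_re.search(seq))


def dinucleotide_shuffle(sequence: str, seed=None) -> str:
    """Shuffle preserving the exact dinucleotide composition.

    Altschul-Erickson Eulerian-path shuffle: the sequence is a walk on
    the graph whose edges are its dinucleotides; a random last-edge
    arborescence into the terminal base is drawn, remaining edges are
    permuted, and the walk is replayed. Deterministic under a fixed seed.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        return seq
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = list(edges)
    non_terminal = [v for v in vertices if v != last]
    for _ in range(10_000):
        last_edge = {}
        ok = True
        for v in non_terminal:
            targets = edges[v]
            last_edge[v] = targets[int(rng.integers(len(targets)))]
        # every non-terminal vertex must reach `last` via last-edge hops
        for v in non_terminal:
            seen = set()
            cur = v
            while cur != last:
                if cur in seen or cur not in last_edge:
                    ok = False
                    break
                seen.add(cur)
                cur = last_edge[cur]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely on DNA alphabets
        raise RuntimeError("failed to sample a valid Eulerian arborescence")
    shuffled_edges: dict[str, list[str]] = {}
    for v, targets in edges.items():
        rest = list(targets)
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        ordered = [rest[i] for i in perm]
        if v in last_edge:
            ordered.append(last_edge[v])
        shuffled_edges[v] = ordered
    out = [first]
    cursors = {v: 0 for v in shuffled_edges}
    cur = first
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][cursors[cur]]
        cursors[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


@dataclass
class EnrichmentResult:
    """Sequence-level motif enrichment of foreground vs background."""

    n_foreground: int
    k_foreground: int  # sequences with >= 1 hit
    n_background: int
    k_background: int
    fold_enrichment: float
    pvalue: float
    infinite_fold: bool = False
    qvalue: float | None = None

    @property
    def foreground_fraction(self) -> float:
        return self.k_foreground / self.n_foreground

    @property
    def background_fraction(self) -> float:
        return self.k_background / self.n_background


def make_shuffled_background(
    foreground: Sequence[str], n_shuffles: int = 10, seed=None
) -> list[str]:
    """Default background: dinucleotide shuffles of every foreground sequence."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for seq in foreground:
        for _ in range(n_shuffles):
            out.append(dinucleotide_shuffle(seq, rng))
    return out


def enrichment_test(
    motif: IupacMotif,
    foreground: Sequence[str],
    background: Sequence[str] | None = None,
    both_strands: bool = True,
    seed=None,
) -> EnrichmentResult:
    """One-sided binomial test of the foreground hit fraction.

    The statistic is the fraction of sequences with at least one hit;
    the foreground count is tested against the background fraction with
    a one-sided (greater) binomial test. When no background is supplied,
    10 dinucleotide shuffles per foreground sequence are generated; the
    10x background keeps the plug-in background fraction precise enough
    for the binomial reference to be well calibrated.
    """
    if not foreground:
        raise ValidationError("foreground sequence set is empty")
    if background is None:
        background = make_shuffled_background(foreground, seed=seed)
    if not background:
        raise ValidationError("background sequence set is empty")
    k_fg = sum(has_hit(motif, s, both_strands) for s in foreground)
    k_bg = sum(has_hit(motif, s, both_strands) for s in background)
    n_fg, n_bg = len(foreground), len(background)
    bg_frac = k_bg / n_bg
    infinite = False
    if bg_frac == 0.0:
        if k_fg > 0:
            pvalue = math.nextafter(0.0, 1.0)
            fold = math.inf
            infinite = True
        else:
            pvalue = 1.0
            fold = 1.0
    else:
        pvalue = float(
            stats.binomtest(k_fg, n_fg, bg_frac, alternative="greater").pvalue
        )
        fold = (k_fg / n_fg) / bg_frac
    return EnrichmentResult(
        n_foreground=n_fg,
        k_foreground=k_fg,
        n_background=n_bg,
        k_background=k_bg,
        fold_enrichment=fold,
        pvalue=pvalue,
        infinite_fold=infinite,
    )


def adjust_qvalues(results: Sequence[EnrichmentResult]) -> None:
    """Benjamini-Hochberg q-values across multiple motifs, set in place."""
    from statsmodels.stats.multitest import multipletests

    if not results:
        return
    q = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
    for r, qi in zip(results, q):
        r.qvalue = float(qi)


def sample_motif_instance(motif: IupacMotif, rng: np.random.Generator) -> str:
    """A concrete sequence drawn uniformly from the motif's degeneracy sets."""
    out = []
    for allowed in motif._sets:
        choices = sorted(allowed)
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)
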