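"""Promoter motif scanning, empirical enrichment, and CRE binding frequency.

Motifs are degenerate IUPAC consensi (no PWMs): a promoter window matches
when every base falls in the code's set. Overlapping windows all count; by
default both strands are scanned (the reverse complement of the motif on
the forward sequence), and a self-reverse-complementary site therefore
counts twice. ``N`` in a sequence matches only motif code ``N``.

Enrichment is empirical: the number of target promoters with at least one
site is compared against the same statistic over R random same-size cohorts
drawn from a background promoter set, with the add-one estimator
p = (1 + #{null >= observed}) / (R + 1).

The per-module cis-regulatory element (CRE) binding frequency is
F = (total sites x motif length) / (module gene count x 100).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from fiberatlas.data_io import IUPAC_CODES, IUPACMotif, ValidationError

#: IUPAC complement (degenerate codes map to the complement of their set).
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


@dataclass
class MotifScanResult:
    motif_id: str
    gene_id: str
    positions: list[int] = field(default_factory=list)  # 0-based starts
    strands: list[str] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class EnrichmentResult:
    motif_id: str
    target_hits: int
    null_hits: np.ndarray
    empirical_p: float


def reverse_complement_motif(consensus: str) -> str:
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(consensus.upper()))


def _motif_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping windows are all reported
    classes = []
    for code in consensus:
        bases = IUPAC_CODES[code]
        classes.append("[" + "".join(sorted(bases)) + "]")
    return re.compile("(?=" + "".join(classes) + ")")


def iupac_scan(
    promoter: str,
    motif: IUPACMotif,
    both_strands: bool = True,
    gene_id: str = "",
) -> MotifScanResult:
    """Scan one promoter for a degenerate consensus.

    Every (possibly overlapping) matching window is a site. With
    ``both_strands`` the reverse complement of the motif is also matched on
    the forward sequence; a window matching on both strands counts twice.
    Positions are 0-based forward-strand start offsets, sorted, with '-'
    after '+' at equal positions.
    """
    seq = str(promoter).upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"sequence contains non-ACGTN characters {sorted(bad)}")
    hits: list[tuple[int, str]] = []
    for m in _motif_regex(motif.consensus).finditer(seq):
        hits.append((m.start(), "+"))
    if both_strands:
        rc = reverse_complement_motif(motif.consensus)
        for m in _motif_regex(rc).finditer(seq):
            hits.append((m.start(), "-"))
    hits.sort(key=lambda h: (h[0], h[1]))
    res = MotifScanResult(motif_id=motif.motif_id, gene_id=gene_id)
    res.positions = [p for p, _ in hits]
    res.strands = [s for _, s in hits]
    return res


def scan_promoter_set(
    promoters: Mapping[str, str],
    motif: IUPACMotif,
    both_strands: bool = True,
) -> list[MotifScanResult]:
    return [
        iupac_scan(seq, motif, both_strands=both_strands, gene_id=gid)
        for gid, seq in promoters.items()
    ]


def _has_site(seq: str, motif: IUPACMotif, both_strands: bool) -> bool:
    s = str(seq).upper()
    if _motif_regex(motif.consensus).search(s):
        return True
    if both_strands and _motif_regex(reverse_complement_motif(motif.consensus)).search(s):
        return True
    return False


def empirical_enrichment(
    target_promoters: Mapping[str, str] | Sequence[str],
    background_promoters: Mapping[str, str] | Sequence[str],
    motif: IUPACMotif,
    R: int = 1000,
    seed: int | None = None,
    both_strands: bool = True,
) -> EnrichmentResult:
    """Empirical enrichment of a motif in target vs background promoters.

    Statistic: promoters with >= 1 site. R random cohorts of |target|
    promoters are drawn from the background without replacement with a
    seeded generator; p = (1 + #{null >= observed}) / (R + 1), so the
    smallest attainable p is 1/(R+1).
    """
    if R < 1:
        raise ValidationError("R must be >= 1")
    targets = (
        list(target_promoters.values())
        if isinstance(target_promoters, Mapping)
        else list(target_promoters)
    )
    background = (
        list(background_promoters.values())
        if isinstance(background_promoters, Mapping)
        else list(background_promoters)
    )
    n_t, n_b = len(targets), len(background)
    if n_b < n_t:
        raise ValidationError(
            f"background ({n_b}) smaller than target ({n_t})"
        )
    target_hits = sum(_has_site(s, motif, both_strands) for s in targets)
    bg_has = np.array(
        [_has_site(s, motif, both_strands) for s in background], dtype=int
    )
    rng = np.random.default_rng(seed)
    null_hits = np.empty(R, dtype=int)
    for r in range(R):
        idx = rng.choice(n_b, size=n_t, replace=False)
        null_hits[r] = int(bg_has[idx].sum())
    p = (1 + int((null_hits >= target_hits).sum())) / (R + 1)
    return EnrichmentResult(
        motif_id=motif.motif_id,
        target_hits=int(target_hits),
        null_hits=null_hits,
        empirical_p=float(p),
    )


def cre_binding_frequency(
    scan_results: Sequence[MotifScanResult] | Sequence[int],
    motif_len: int,
    n_genes: int,
) -> float:
    """Per-module CRE binding frequency.

    F = (sum of site counts over the module's promoters x motif length)
    / (module gene count x 100). On this scale 0.05 corresponds to, e.g.,
    50 sites of a 10-bp motif over a 100-gene module.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    if motif_len < 1:
        raise ValidationError("motif_len must be >= 1")
    counts = [
        r.n_sites if isinstance(r, MotifScanResult) else int(r)
        for r in scan_results
    ]
    total = int(sum(counts))
    return float(total * motif_len) / (n_genes * 100.0)
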