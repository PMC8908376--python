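"""At/Dt homeolog pairing and subgenome prominence.

Allotetraploid cotton carries two gene copies per ancestral locus, one from
each diploid progenitor subgenome (At, Dt). A gene is called
subgenome-prominent when its expression exceeds its homeolog's, i.e. the
pseudocounted expression ratio r = (at + c)/(dt + c) departs from 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from fiberatlas.data_io import ValidationError, parse_subgenome

_POSITIONAL_RE = re.compile(r"^Ghir_([AD])(\d{2})(G\d+)$")


@dataclass
class HomeologPair:
    at_gene_id: str
    dt_gene_id: str
    at_expr: float = float("nan")
    dt_expr: float = float("nan")
    ratio: float = float("nan")
    prominence: str = "undetermined"

    def __post_init__(self) -> None:
        if parse_subgenome(self.at_gene_id) != "At":
            raise ValidationError(f"{self.at_gene_id} is not an At gene id")
        if parse_subgenome(self.dt_gene_id) != "Dt":
            raise ValidationError(f"{self.dt_gene_id} is not a Dt gene id")


def pair_homeologs(
    gene_ids: Iterable[str],
    pair_table: str | Path | pd.DataFrame | None = None,
) -> tuple[list[HomeologPair], list[str]]:
    """Pair At genes with their Dt homeologs.

    An explicit two-column pair table (at_gene_id, dt_gene_id) takes
    precedence. Otherwise the positional-id heuristic applies:
    ``Ghir_Axx Gyyyyyy`` pairs with ``Ghir_Dxx Gyyyyyy`` when both ids are
    present. Returns (pairs, unpaired_gene_ids).
    """
    gene_ids = list(dict.fromkeys(str(g) for g in gene_ids))
    if pair_table is not None:
        if not isinstance(pair_table, pd.DataFrame):
            pair_table = pd.read_csv(pair_table, sep="\t", dtype=str)
        pairs = []
        paired: set[str] = set()
        for _, row in pair_table.iterrows():
            a, d = str(row.iloc[0]), str(row.iloc[1])
            sub = {parse_subgenome(a), parse_subgenome(d)}
            if sub != {"At", "Dt"}:
                raise ValidationError(
                    f"pair table row ({a}, {d}) is not one At + one Dt gene"
                )
            if parse_subgenome(a) == "Dt":
                a, d = d, a
            pairs.append(HomeologPair(a, d))
            paired.update((a, d))
        unpaired = [g for g in gene_ids if g not in paired]
        return pairs, unpaired

    by_key: dict[tuple[str, str], dict[str, str]] = {}
    nonconforming = []
    for g in gene_ids:
        m = _POSITIONAL_RE.match(g)
        if m is None:
            nonconforming.append(g)
            continue
        sub, chrom_num, gnum = m.groups()
        by_key.setdefault((chrom_num, gnum), {})[sub] = g
    pairs = []
    unpaired = list(nonconforming)
    for key in sorted(by_key):
        slot = by_key[key]
        if "A" in slot and "D" in slot:
            pairs.append(HomeologPair(slot["A"], slot["D"]))
        else:
            unpaired.extend(slot.values())
    return pairs, unpaired


def classify_prominence(pair: HomeologPair, pseudocount: float = 1.0) -> HomeologPair:
    """Assign prominence from the pseudocounted expression ratio.

    r = (at_expr + c)/(dt_expr + c): At-prominent if r > 1, Dt-prominent if
    r < 1, balanced if r = 1; undetermined when either value is missing.
    The bare ratio rule is recovered for positive values as c -> 0.
    """
    at, dt = pair.at_expr, pair.dt_expr
    if not np.isnan(at) and at < 0 or not np.isnan(dt) and dt < 0:
        raise ValidationError("expression must be non-negative")
    if np.isnan(at) or np.isnan(dt):
        pair.ratio = float("nan")
        pair.prominence = "undetermined"
        return pair
    r = (at + pseudocount) / (dt + pseudocount)
    pair.ratio = float(r)
    if r > 1:
        pair.prominence = "At"
    elif r < 1:
        pair.prominence = "Dt"
    else:
        pair.prominence = "balanced"
    return pair


def prominence_table(
    expression: pd.Series,
    gene_ids: Iterable[str] | None = None,
    pair_table=None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pair and classify a whole gene set against a pooled expression vector.

    ``expression`` maps gene_id -> pooled expression (typically OF). Genes
    absent from the vector get missing expression and come out
    undetermined.
    """
    if gene_ids is None:
        gene_ids = list(expression.index)
    pairs, unpaired = pair_homeologs(gene_ids, pair_table=pair_table)
    rows = []
    for p in pairs:
        p.at_expr = float(expression.get(p.at_gene_id, np.nan))
        p.dt_expr = float(expression.get(p.dt_gene_id, np.nan))
        classify_prominence(p, pseudocount=pseudocount)
        rows.append(
            {
                "at_gene_id": p.at_gene_id,
                "dt_gene_id": p.dt_gene_id,
                "at_expr": p.at_expr,
                "dt_expr": p.dt_expr,
                "ratio": p.ratio,
                "prominence": p.prominence,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["at_gene_id", "dt_gene_id", "at_expr", "dt_expr", "ratio", "prominence"],
    )
    out.attrs["n_unpaired"] = len(unpaired)
    out.attrs["unpaired"] = unpaired
    return out
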