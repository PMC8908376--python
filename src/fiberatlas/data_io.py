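"""File formats and the shared data model.

All tabular inputs are TSV with a header row. Expression values are FPKM or
log2(FPKM+1); empty cells are *missing*, which is deliberately distinct from
zero (an unquantified transcript is not an unexpressed one, and the
distinction changes EET tiering). Gene models arrive as GTF (1-based
inclusive, as the dialect defines); internal coordinate arithmetic is 0-based
half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

IUPAC_CODES: dict[str, frozenset[str]] = {
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
    "N": frozenset("ACGTN"),  # N in a sequence matches only motif code N
}

OF_TISSUES = frozenset({"ovule", "fiber"})
LRS_TISSUES = frozenset({"leaf", "root", "seed"})

_SUBGENOME_RE = re.compile(r"^Ghir_([AD])\d{2}G\d+")
_TRANSCRIPT_SUFFIX_RE = re.compile(r"\.(\d+)$")


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending cell."""


# ---------------------------------------------------------------------------
# Expression matrix


@dataclass
class ExpressionMatrix:
    """Features x samples non-negative expression with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by feature_id with sample_id columns. ``NaN``
        marks a missing measurement, never a zero.
    level
        ``"gene"`` or ``"transcript"``.
    unit
        ``"fpkm"`` (linear) or ``"log2fpkm1"`` (log2(FPKM+1)).
    """

    values: pd.DataFrame
    level: str = "gene"
    unit: str = "fpkm"

    def __post_init__(self) -> None:
        if self.level not in ("gene", "transcript"):
            raise ValidationError(f"unknown level {self.level!r}")
        if self.unit not in ("fpkm", "log2fpkm1"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative expression values present")
        self.values.index.name = "feature_id"
        self.values.columns.name = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_log2(self) -> "ExpressionMatrix":
        """Return a log2(FPKM+1) view; identity if already on that scale."""
        if self.unit == "log2fpkm1":
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), self.level, "log2fpkm1")

    def subset(
        self,
        features: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "ExpressionMatrix":
        df = self.values
        if features is not None:
            features = list(features)
            missing = set(features) - set(df.index)
            if missing:
                raise KeyError(f"features absent from matrix: {sorted(missing)[:5]}")
            df = df.loc[features]
        if samples is not None:
            samples = list(samples)
            missing = set(samples) - set(df.columns)
            if missing:
                raise KeyError(f"samples absent from matrix: {sorted(missing)[:5]}")
            df = df[samples]
        return ExpressionMatrix(df, self.level, self.unit)

    def write_tsv(self, path: str | Path) -> None:
        """Write TSV; missing values become empty cells (round-trip safe)."""
        self.values.to_csv(path, sep="\t", na_rep="")


def load_expression_matrix(
    path: str | Path, level: str = "gene", unit: str = "fpkm"
) -> ExpressionMatrix:
    """Load a features x samples TSV into an :class:`ExpressionMatrix`.

    The first column holds feature ids, the header row sample ids. Empty
    cells become missing (NaN), not zero. Malformed numeric cells and
    duplicate feature ids are rejected with the offending location named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].str.strip()
        parsed = pd.to_numeric(raw.mask(raw == ""), errors="coerce")
        bad = parsed.isna() & (raw != "")
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: malformed numeric cell at row {row!r}, column {col!r}"
            )
        numeric[col] = parsed
    return ExpressionMatrix(numeric, level=level, unit=unit)


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass
class SampleSheet:
    """Sample metadata with the derived OF / LRS / excluded grouping.

    OF pools ovule + fiber (fiber-relevant tissue); LRS pools
    leaf + root + seed (non-fiber background). Any other tissue is excluded
    from the two-group contrast but kept on the sheet.
    """

    table: pd.DataFrame  # columns: sample_id, tissue, dpa, cultivar, group

    REQUIRED = ("sample_id", "tissue", "dpa", "cultivar")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        if "group" not in self.table.columns:
            self.table = self.table.assign(
                group=self.table["tissue"].map(derive_group)
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    def dpa_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["dpa"].iloc[0])

    def validate_against(self, expr: ExpressionMatrix) -> None:
        unknown = set(expr.sample_ids) - set(self.sample_ids)
        if unknown:
            raise ValidationError(
                f"samples missing from sheet: {sorted(unknown)[:5]}"
            )

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def derive_group(tissue: str) -> str:
    t = str(tissue).strip().lower()
    if t in OF_TISSUES:
        return "OF"
    if t in LRS_TISSUES:
        return "LRS"
    return "excluded"


def load_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# Gene models and promoters


@dataclass
class GeneModel:
    """A gene with its TSS and transcript children.

    ``tss`` is 1-based genomic; for a multi-transcript gene it is the
    strand-most-5' transcript start (smallest start on +, largest end on -).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    transcript_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if self.tss < 1:
            raise ValidationError(f"{self.gene_id}: tss must be >= 1")


_GTF_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF transcript features.

    Only ``transcript`` (or ``mRNA``) rows are needed; the TSS is taken as
    the strand-most-5' transcript start among a gene's transcripts.
    """
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{ln}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature not in ("transcript", "mRNA"):
                continue
            attr = dict(_GTF_ATTR_RE.findall(attrs))
            gene_id = attr.get("gene_id")
            tx_id = attr.get("transcript_id")
            if gene_id is None:
                raise ParseError(f"{path}:{ln}: missing gene_id attribute")
            start_i, end_i = int(start), int(end)
            five_prime = start_i if strand == "+" else end_i
            rec = per_gene.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "tss": five_prime, "tx": []},
            )
            if strand == "+":
                rec["tss"] = min(rec["tss"], five_prime)
            else:
                rec["tss"] = max(rec["tss"], five_prime)
            if tx_id:
                rec["tx"].append(tx_id)
    return [
        GeneModel(g, r["chrom"], r["strand"], r["tss"], r["tx"])
        for g, r in per_gene.items()
    ]


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA genome into an uppercase chrom -> sequence mapping."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def extract_promoters(
    gene_models: Iterable[GeneModel],
    genome: Mapping[str, str],
    window: int = 1000,
) -> dict[str, str]:
    """Extract the ``window`` bp upstream of each gene's TSS.

    On the + strand this is genome[tss-window .. tss-1] (1-based inclusive);
    on the - strand the reverse complement of genome[tss+1 .. tss+window].
    Sequences truncated at a chromosome edge are returned shorter. Output is
    uppercased (softmasking dropped).
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    out: dict[str, str] = {}
    for gm in gene_models:
        if gm.chrom not in genome:
            raise KeyError(f"{gm.gene_id}: chromosome {gm.chrom!r} not in genome")
        chrom_seq = genome[gm.chrom]
        if gm.tss > len(chrom_seq):
            raise ValidationError(
                f"{gm.gene_id}: tss {gm.tss} beyond chromosome "
                f"length {len(chrom_seq)}"
            )
        if gm.strand == "+":
            lo = max(0, gm.tss - 1 - window)  # 0-based half-open [lo, tss-1)
            seq = chrom_seq[lo : gm.tss - 1]
        else:
            seq = chrom_seq[gm.tss : gm.tss + window]
            seq = str(Seq(seq).reverse_complement())
        out[gm.gene_id] = seq.upper()
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Motif library


@dataclass
class IUPACMotif:
    """A degenerate consensus over the IUPAC nucleotide alphabet."""

    motif_id: str
    consensus: str
    tf_family: str = ""

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        if len(self.consensus) < 1:
            raise ValidationError(f"{self.motif_id}: empty consensus")
        bad = set(self.consensus) - set(IUPAC_CODES)
        if bad:
            raise ValidationError(
                f"{self.motif_id}: invalid IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.consensus)


#: Consensus motifs recovered from fiber-specific promoter analysis
#: (bHLH / C2H2 / AP2-ERF / MADS / Myb-SANT / HMG families).
DEFAULT_MOTIF_LIBRARY: tuple[tuple[str, str, str], ...] = (
    ("M01", "YYYCAHCHCC", "bHLH"),
    ("M02", "YTTTCTTTYT", "C2H2"),
    ("M03", "RRAAAAGAAR", "C2H2"),
    ("M04", "RAARAAGAAR", "C2H2"),
    ("M05", "GRKGGKGGWG", "AP2/ERF"),
    ("M06", "CYCYBCCTCC", "AP2/ERF"),
    ("M07", "RAAAAAGAAA", "C2H2"),
    ("M08", "TYTYTYTCYY", "C2H2"),
    ("M09", "CHCCAYCHC", "AP2/ERF"),
    ("M10", "GGKGKKGGAG", "C2H2"),
    ("M11", "RAARAAGAA", "MADS-box"),
    ("M12", "YTTYYHTTTC", "HMG"),
    ("M13", "SCMMHGCC", "AP2/ERF"),
    ("M14", "CHYCHCCACC", "Myb/SANT"),
    ("M15", "AAAAARAAA", "MADS-box"),
)


def default_motif_library() -> list[IUPACMotif]:
    return [IUPACMotif(m, c, f) for m, c, f in DEFAULT_MOTIF_LIBRARY]


def load_motif_library(path: str | Path) -> list[IUPACMotif]:
    """Read a motif library TSV with columns motif_id, consensus, tf_family."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("motif_id", "consensus"):
        if col not in df.columns:
            raise ParseError(f"{path}: motif library needs column {col!r}")
    return [
        IUPACMotif(r["motif_id"], r["consensus"], r.get("tf_family", ""))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Identifier conventions


def parse_subgenome(feature_id: str) -> str:
    """Classify a Ghir-style id into the At or Dt subgenome.

    Allotetraploid cotton ids encode the subgenome in the chromosome code
    (``Ghir_A10G001030`` vs ``Ghir_D01G000100``); a transcript suffix
    ``.n`` is ignored. Anything else is ``"unknown"`` (a value, not an
    error: scaffolds and supertranscripts are expected).
    """
    m = _SUBGENOME_RE.match(str(feature_id))
    if m is None:
        return "unknown"
    return "At" if m.group(1) == "A" else "Dt"


def transcript_gene_id(transcript_id: str) -> str:
    """Strip the ``.n`` transcript suffix to recover the parent gene id."""
    return _TRANSCRIPT_SUFFIX_RE.sub("", str(transcript_id))


def transcript_suffix(transcript_id: str) -> int:
    m = _TRANSCRIPT_SUFFIX_RE.search(str(transcript_id))
    return int(m.group(1)) if m else 0
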