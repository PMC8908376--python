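"""Synthetic inputs with planted, recoverable structure.

Generates everything the pipeline consumes — gene- and transcript-level
FPKM matrices over a fiber developmental time course, sample sheets,
promoters with planted degenerate motifs, and nCounter-style counts paired
with fiber traits — together with truth tables, so every downstream stage
can be tested as a parameter-recovery problem without any external data.

The expression model works on the log2(FPKM+1) scale: a module gene's
latent value is its module's stage-profile mean at the sample's DPA plus a
per-module per-DPA deviation (within-stage biological variation) plus
i.i.d. Gaussian gene/sample noise; FPKM = 2^latent - 1, floored at zero.
Fiber-specific (module) genes sit at a low baseline in the non-fiber LRS
tissues. Homeolog pairs share a module profile with the At copy shifted up
by log2(bias_fold). A chosen subset of genes carries one extra OF-exclusive
transcript variant whose LRS values are exactly zero. Noise is Gaussian on
the log scale rather than count-based because the pipeline consumes
FPKM-quantified tables, not reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fiberatlas.data_io import (
    ExpressionMatrix,
    IUPACMotif,
    SampleSheet,
    ValidationError,
    write_fasta,
)
from fiberatlas.stages import map_dpa_to_stage, stage_tokens

#: Default module sizes: six fiber-upregulated modules plus 8 outlier genes.
DEFAULT_MODULE_SIZES = (128, 61, 35, 27, 25, 18)

#: Stage-mean caricatures (log2(FPKM+1)) over
#: (commitment, initiation, elongation, scw), matched to the default sizes:
#: the two largest modules peak at elongation/SCW, two mid-size at
#: initiation/elongation, two at commitment — so eigengene clades split 2:4.
DEFAULT_STAGE_PROFILES = (
    (1.0, 2.0, 5.0, 4.0),
    (1.0, 1.5, 4.0, 5.0),
    (2.0, 4.5, 3.5, 1.0),
    (5.0, 3.0, 1.0, 1.0),
    (1.5, 4.0, 4.5, 1.5),
    (4.5, 3.5, 1.0, 0.5),
)

_STAGE_INDEX = {"commitment": 0, "initiation": 1, "elongation": 2, "scw": 3}


@dataclass
class SimulationConfig:
    """All knobs of the generator; every random draw flows from ``seed``."""

    seed: int = 0
    n_genes: int = 302
    module_sizes: tuple = DEFAULT_MODULE_SIZES
    stage_mean_profiles: tuple = DEFAULT_STAGE_PROFILES
    noise_sd: float = 0.5          # per-gene per-sample, log2 scale
    # Per-module per-DPA deviation. Sized so module-specific variance is
    # comparable to the stage-profile variance: under an *unsigned* network
    # |r|^beta, modules with proportional or anti-proportional stage
    # profiles are indistinguishable unless each carries variation of its
    # own, so this bounds between-module |r| well away from 1.
    within_stage_sd: float = 1.5
    n_samples_per_dpa: int = 3
    n_lrs_per_tissue: int = 6
    lrs_baseline: float = 0.5      # log2(FPKM+1) of fiber genes in LRS
    outlier_baseline: float = 2.0  # non-module genes, both groups
    homeolog_fraction: float = 0.3
    bias_fold: float = 2.0
    eet_genes: int = 20
    motif_plant_rate: float = 0.9
    promoter_len: int = 1000
    n_target_promoters: int = 50
    n_background_promoters: int = 200
    trait_r: dict = field(default_factory=lambda: {"fiber_length_mm": 0.6})
    n_genotypes: int = 100
    control_effect_sd: float = 0.3  # lognormal per-sample technical effect

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValidationError("module sizes exceed n_genes")
        if len(self.stage_mean_profiles) != len(self.module_sizes):
            raise ValidationError("one stage profile per module required")
        if not 0 <= self.motif_plant_rate <= 1:
            raise ValidationError("motif_plant_rate must be in [0, 1]")
        if not 0 <= self.homeolog_fraction <= 1:
            raise ValidationError("homeolog_fraction must be in [0, 1]")
        for r in self.trait_r.values():
            if not -1 < r < 1:
                raise ValidationError("planted trait_r must be in (-1, 1)")
        if self.eet_genes > sum(self.module_sizes):
            raise ValidationError("eet_genes exceeds module gene count")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass
class SimulatedExpression:
    gene_expr: ExpressionMatrix        # FPKM, genes x samples
    transcript_expr: ExpressionMatrix  # FPKM, transcripts x samples
    sheet: SampleSheet
    truth: dict  # modules, homeologs, eets, stage_profiles


def _module_labels(n: int) -> list[str]:
    from fiberatlas.coexpr import MODULE_COLORS

    return [
        MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
        for i in range(n)
    ]


def _gene_ids(config: SimulationConfig, rng: np.random.Generator) -> tuple[list[str], pd.DataFrame]:
    """Assign Ghir-style ids; a fraction of genes form At/Dt positional pairs.

    Pair members are adjacent gene slots (hence usually same module); the
    At copy is the planted-biased one. Returns ids per slot and the
    homeolog truth table.
    """
    n = config.n_genes
    n_pairs = int(n * config.homeolog_fraction) // 2
    ids = [""] * n
    pairs = []
    slot = 0
    pair_idx = 0
    while pair_idx < n_pairs and slot + 1 < n:
        chrom = (pair_idx % 13) + 1
        gnum = (pair_idx // 13 + 1) * 100 + (pair_idx % 13)
        a = f"Ghir_A{chrom:02d}G{gnum:06d}"
        d = f"Ghir_D{chrom:02d}G{gnum:06d}"
        ids[slot], ids[slot + 1] = a, d
        pairs.append({"at_gene_id": a, "dt_gene_id": d, "at_slot": slot, "dt_slot": slot + 1})
        slot += 2
        pair_idx += 1
    single_idx = 0
    for s in range(n):
        if ids[s]:
            continue
        sub = "A" if single_idx % 2 == 0 else "D"
        chrom = (single_idx % 13) + 1
        gnum = 500000 + single_idx  # range disjoint from the paired ids
        ids[s] = f"Ghir_{sub}{chrom:02d}G{gnum:06d}"
        single_idx += 1
    return ids, pd.DataFrame(pairs)


def simulate_expression(config: SimulationConfig) -> SimulatedExpression:
    """Expression matrices + sample sheet + truth tables."""
    config.validate()
    rng = _rng(config.seed, 0)

    # --- samples -----------------------------------------------------------
    tokens = list(stage_tokens())
    sample_rows = []
    for tok in tokens:
        stage = map_dpa_to_stage(tok)
        tissue = "ovule" if stage in ("commitment", "initiation") else "fiber"
        for i in range(config.n_samples_per_dpa):
            sample_rows.append(
                {
                    "sample_id": f"OF_{tok}_{i + 1}",
                    "tissue": tissue,
                    "dpa": f"{tok} DPA",
                    "cultivar": "TM-1",
                }
            )
    for tissue in ("leaf", "root", "seed"):
        for i in range(config.n_lrs_per_tissue):
            sample_rows.append(
                {
                    "sample_id": f"LRS_{tissue}_{i + 1}",
                    "tissue": tissue,
                    "dpa": "",
                    "cultivar": "TM-1",
                }
            )
    sheet = SampleSheet(pd.DataFrame(sample_rows))
    of_samples = [r["sample_id"] for r in sample_rows if r["sample_id"].startswith("OF_")]
    lrs_samples = [r["sample_id"] for r in sample_rows if r["sample_id"].startswith("LRS_")]
    sample_token = {r["sample_id"]: r["dpa"].replace(" DPA", "") for r in sample_rows}

    # --- gene-level structure ---------------------------------------------
    gene_ids, homeolog_truth = _gene_ids(config, rng)
    labels = _module_labels(config.n_modules)
    module_of_slot: list[str] = []
    for lab, size in zip(labels, config.module_sizes):
        module_of_slot.extend([lab] * size)
    module_of_slot.extend(["unassigned"] * (config.n_genes - len(module_of_slot)))

    # per-module per-DPA deviation: biological variation within a stage
    dev = {
        lab: dict(zip(tokens, rng.normal(0.0, config.within_stage_sd, len(tokens))))
        for lab in labels
    }
    profile_of = dict(zip(labels, config.stage_mean_profiles))

    at_biased_slots = set(homeolog_truth["at_slot"]) if len(homeolog_truth) else set()
    bias_shift = float(np.log2(config.bias_fold))

    n_of, n_lrs = len(of_samples), len(lrs_samples)
    latent_of = np.empty((config.n_genes, n_of))
    latent_lrs = np.empty((config.n_genes, n_lrs))
    for g in range(config.n_genes):
        mod = module_of_slot[g]
        shift = bias_shift if g in at_biased_slots else 0.0
        if mod == "unassigned":
            mu_of = np.full(n_of, config.outlier_baseline + shift)
            mu_lrs = np.full(n_lrs, config.outlier_baseline + shift)
        else:
            prof = profile_of[mod]
            mu_of = np.array(
                [
                    prof[_STAGE_INDEX[map_dpa_to_stage(sample_token[s])]]
                    + dev[mod][sample_token[s]]
                    + shift
                    for s in of_samples
                ]
            )
            mu_lrs = np.full(n_lrs, config.lrs_baseline + shift)
        latent_of[g] = mu_of + rng.normal(0.0, config.noise_sd, n_of)
        latent_lrs[g] = mu_lrs + rng.normal(0.0, config.noise_sd, n_lrs)

    latent = np.hstack([latent_of, latent_lrs])
    fpkm = np.maximum(np.exp2(np.maximum(latent, 0.0)) - 1.0, 0.0)
    all_samples = of_samples + lrs_samples
    gene_expr = ExpressionMatrix(
        pd.DataFrame(fpkm, index=pd.Index(gene_ids, name="feature_id"), columns=all_samples),
        level="gene",
        unit="fpkm",
    )

    # --- transcript-level expansion with EET variants ----------------------
    module_slots = [g for g in range(config.n_genes) if module_of_slot[g] != "unassigned"]
    eet_slots = rng.choice(module_slots, size=config.eet_genes, replace=False)
    eet_slots = set(int(s) for s in eet_slots)

    tx_rows = []
    tx_ids = []
    eet_tx = []
    for g, gid in enumerate(gene_ids):
        n_var = int(rng.integers(1, 5))
        gene_vals = fpkm[g]
        tx_ids.append(f"{gid}.1")
        tx_rows.append(gene_vals)
        for v in range(2, n_var + 1):
            frac = rng.uniform(0.1, 0.6)
            tx_ids.append(f"{gid}.{v}")
            tx_rows.append(gene_vals * frac)
        if g in eet_slots:
            suffix = n_var + 1
            frac = rng.uniform(0.2, 0.8)
            vals = gene_vals * frac
            vals[n_of:] = 0.0  # exactly zero in every LRS sample
            # keep OF support strictly positive so the pooled OF value is > 0
            vals[:n_of] = np.maximum(vals[:n_of], 0.01)
            tx_id = f"{gid}.{suffix}"
            tx_ids.append(tx_id)
            tx_rows.append(vals)
            eet_tx.append(tx_id)
    transcript_expr = ExpressionMatrix(
        pd.DataFrame(
            np.vstack(tx_rows), index=pd.Index(tx_ids, name="feature_id"), columns=all_samples
        ),
        level="transcript",
        unit="fpkm",
    )

    # realized stage means: profile + the drawn per-DPA deviations, averaged
    # over the OF samples of each stage (what a perfect profiler would see)
    stage_of_sample = {s: map_dpa_to_stage(sample_token[s]) for s in of_samples}
    realized = {}
    for lab in labels:
        prof = profile_of[lab]
        row = {}
        for stage_name, si in _STAGE_INDEX.items():
            samples = [s for s in of_samples if stage_of_sample[s] == stage_name]
            row[stage_name] = float(
                np.mean([prof[si] + dev[lab][sample_token[s]] for s in samples])
            )
        realized[lab] = row
    realized_df = pd.DataFrame(realized).T.rename_axis("module")

    truth = {
        "modules": pd.DataFrame(
            {"gene_id": gene_ids, "module": module_of_slot}
        ),
        "realized_stage_means": realized_df,
        "homeologs": homeolog_truth.assign(bias_fold=config.bias_fold)
        if len(homeolog_truth)
        else pd.DataFrame(columns=["at_gene_id", "dt_gene_id", "bias_fold"]),
        "eets": pd.DataFrame({"transcript_id": eet_tx}),
        "stage_profiles": pd.DataFrame(
            list(config.stage_mean_profiles),
            index=pd.Index(labels, name="module"),
            columns=["commitment", "initiation", "elongation", "scw"],
        ),
    }
    return SimulatedExpression(gene_expr, transcript_expr, sheet, truth)


def realize_consensus(motif: IUPACMotif, rng: np.random.Generator) -> str:
    """Draw one concrete ACGT word from a degenerate consensus."""
    out = []
    for code in motif.consensus:
        from fiberatlas.data_io import IUPAC_CODES

        bases = sorted(IUPAC_CODES[code] - {"N"}) or list("ACGT")
        out.append(bases[int(rng.integers(len(bases)))])
    return "".join(out)


def simulate_promoters(
    config: SimulationConfig, motif: IUPACMotif
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Target and background promoter sets with planted motif insertions.

    Background promoters are i.i.d. uniform ACGT of ``promoter_len``;
    each target promoter receives one concrete realization of the motif at
    a uniform position with probability ``motif_plant_rate``. Returns
    (targets, background, truth) where truth records the insertions.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    bases = np.array(list("ACGT"))

    def random_seq() -> str:
        return "".join(bases[rng.integers(0, 4, config.promoter_len)])

    background = {
        f"bg_{i + 1}": random_seq() for i in range(config.n_background_promoters)
    }
    targets = {}
    records = []
    for i in range(config.n_target_promoters):
        name = f"target_{i + 1}"
        seq = random_seq()
        planted, pos = False, -1
        if rng.random() < config.motif_plant_rate:
            word = realize_consensus(motif, rng)
            pos = int(rng.integers(0, config.promoter_len - len(word) + 1))
            seq = seq[:pos] + word + seq[pos + len(word):]
            planted = True
        targets[name] = seq
        records.append({"promoter": name, "planted": planted, "position": pos})
    return targets, background, pd.DataFrame(records)


def simulate_ncounter_traits(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """nCounter-style counts, a trait table, and the planted-correlation truth.

    Controls (EF1a-5, UBQ-14, Actin-4) carry a lognormal per-sample
    technical effect that multiplies every count in the sample, which the
    housekeeping-mean normalization must remove. For each entry of
    ``trait_r`` one transcript is drawn bivariate-normal with that trait
    on the latent log2 scale at the requested r; two null transcripts are
    included as negative controls. Counts are Poisson around the latent
    mean.
    """
    config.validate()
    rng = _rng(config.seed, 2)
    genotypes = [f"G{i + 1:03d}" for i in range(config.n_genotypes)]
    sample_effect = np.exp(rng.normal(0.0, config.control_effect_sd, config.n_genotypes))

    counts = {}
    controls = ["EF1a-5", "UBQ-14", "Actin-4"]
    for ctrl in controls:
        base = rng.uniform(400, 800)
        counts[ctrl] = rng.poisson(base * sample_effect)

    traits = {}
    truth_rows = []
    for trait_name, r in config.trait_r.items():
        z = rng.standard_normal(config.n_genotypes)
        eps = rng.standard_normal(config.n_genotypes)
        trait_latent = r * z + np.sqrt(1.0 - r * r) * eps
        tx = f"nc_{trait_name}"
        latent = 8.0 + 1.5 * z
        counts[tx] = rng.poisson(np.exp2(latent) * sample_effect)
        traits[trait_name] = 20.0 + 5.0 * trait_latent
        truth_rows.append({"transcript_id": tx, "trait": trait_name, "planted_r": r})
    for j in range(2):
        tx = f"nc_null_{j + 1}"
        latent = 8.0 + 1.5 * rng.standard_normal(config.n_genotypes)
        counts[tx] = rng.poisson(np.exp2(latent) * sample_effect)
        truth_rows.append({"transcript_id": tx, "trait": "", "planted_r": 0.0})

    counts_df = pd.DataFrame(counts, index=genotypes).T.astype(float)
    counts_df.index.name = "gene_id"
    traits_df = pd.DataFrame(traits, index=pd.Index(genotypes, name="genotype"))
    return counts_df, traits_df, pd.DataFrame(truth_rows)


def write_simulation(config: SimulationConfig, out_dir: str | Path, motif: IUPACMotif | None = None) -> None:
    """Emit every simulated input (and truth tables) as TSV/FASTA files."""
    from fiberatlas.data_io import default_motif_library

    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    sim = simulate_expression(config)
    sim.gene_expr.write_tsv(out / "expr.tsv")
    sim.transcript_expr.write_tsv(out / "transcripts.tsv")
    sim.sheet.write_tsv(out / "samples.tsv")
    for name, df in sim.truth.items():
        keep_index = name in ("stage_profiles", "realized_stage_means")
        df.to_csv(out / "truth" / f"{name}.tsv", sep="\t", index=keep_index)

    library = default_motif_library()
    motif = motif or library[0]
    targets, background, promoter_truth = simulate_promoters(config, motif)
    write_fasta({**targets, **background}, out / "promoters.fa")
    promoter_truth.to_csv(out / "truth" / "promoters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(m.motif_id, m.consensus, m.tf_family) for m in library],
        columns=["motif_id", "consensus", "tf_family"],
    ).to_csv(out / "motifs.tsv", sep="\t", index=False)

    counts, traits, nc_truth = simulate_ncounter_traits(config)
    counts.to_csv(out / "ncounter.tsv", sep="\t")
    traits.to_csv(out / "traits.tsv", sep="\t")
    nc_truth.to_csv(out / "truth" / "ncounter.tsv", sep="\t", index=False)
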