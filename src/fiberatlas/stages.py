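"""Consolidation of DPA timepoints into the four fiber developmental stages.

Cotton fiber development is staged on a days-post-anthesis (DPA) axis:
commitment of ovule epidermal cells (-3 to 0 DPA), initiation (1-3 DPA),
elongation (5-20 DPA) and secondary cell wall synthesis (21-40 DPA). The
mapping is a fixed token table; range tokens such as "15-16" or "25-28"
are single sample labels and are matched literally, not expanded.
"""

from __future__ import annotations

import pandas as pd

from fiberatlas.coexpr import ModulePartition
from fiberatlas.data_io import ExpressionMatrix, SampleSheet

STAGE_ORDER = ("commitment", "initiation", "elongation", "scw")
UNSTAGED = "unstaged"

_STAGE_TOKENS: dict[str, str] = {
    "-3": "commitment",
    "-1": "commitment",
    "0": "commitment",
    "1": "initiation",
    "3": "initiation",
    "5": "elongation",
    "8": "elongation",
    "10": "elongation",
    "12": "elongation",
    "14": "elongation",
    "15-16": "elongation",
    "18": "elongation",
    "20": "elongation",
    "21": "scw",
    "25-28": "scw",
    "30": "scw",
    "35": "scw",
    "40": "scw",
}

#: Unicode dashes normalized to ASCII hyphen before lookup: the minus sign
#: in "-3 DPA" and the en-dash in "25-28 DPA" both appear in the wild.
_DASHES = str.maketrans({"−": "-", "–": "-", "—": "-"})


def stage_tokens() -> dict[str, str]:
    """The fixed DPA-token -> stage table (a copy)."""
    return dict(_STAGE_TOKENS)


def normalize_dpa_token(dpa_label: str) -> str:
    tok = str(dpa_label).translate(_DASHES)
    tok = tok.replace("DPA", "").replace("dpa", "")
    return "".join(tok.split())


def map_dpa_to_stage(dpa_label: str) -> str:
    """Map a DPA label ("0 DPA", "15-16DPA", "-3") to its stage.

    Tokens outside the 18-entry table return ``"unstaged"``.
    """
    return _STAGE_TOKENS.get(normalize_dpa_token(dpa_label), UNSTAGED)


def stage_profile(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    assignments: ModulePartition | pd.Series,
) -> pd.DataFrame:
    """Module x stage mean-expression summary.

    Per module and stage: the mean over member genes of the mean
    log2(FPKM+1) over that stage's samples. A stage with no samples is
    reported missing. The ``peak_stage`` column gives each module's argmax
    stage, ties broken by developmental order (commitment < initiation <
    elongation < scw).
    """
    if isinstance(assignments, ModulePartition):
        assignments = assignments.assignments
    log_expr = expr.to_log2()
    sheet.validate_against(expr)

    stage_samples: dict[str, list[str]] = {s: [] for s in STAGE_ORDER}
    for sid in expr.sample_ids:
        stage = map_dpa_to_stage(sheet.dpa_of(sid))
        if stage in stage_samples:
            stage_samples[stage].append(sid)

    modules = [m for m in assignments.unique() if m != "unassigned"]
    modules.sort()
    rows = {}
    for module in modules:
        members = [
            g for g in assignments.index[assignments == module]
            if g in log_expr.values.index
        ]
        sub = log_expr.values.loc[members]
        prof = {}
        for stage in STAGE_ORDER:
            cols = stage_samples[stage]
            if not cols:
                prof[stage] = float("nan")
            else:
                prof[stage] = float(sub[cols].mean(axis=1).mean())
        rows[module] = prof
    out = pd.DataFrame(rows).T.reindex(columns=list(STAGE_ORDER))
    out.index.name = "module"

    def _argmax(row: pd.Series) -> str:
        present = row.dropna()
        if present.empty:
            return UNSTAGED
        best = present.max()
        for stage in STAGE_ORDER:  # developmental-order tie-break
            if stage in present.index and present[stage] == best:
                return stage
        return UNSTAGED

    out["peak_stage"] = out[list(STAGE_ORDER)].apply(_argmax, axis=1)
    return out
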