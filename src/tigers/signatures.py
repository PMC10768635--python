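"""Single-cell profiles and treatment-vs-control response signatures.

A *profile* is the expression vector of one cell under one drug — after
completion, every (drug, cell) pair has one, including drugs the cell was
never physically treated with.  A *response signature* compares a cell's
treated profile with the same cell's control (DMSO) profile, either as a
log2 ratio (default) or as a plain difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, NumericError
from .tensor_data import ExpressionTensor

__all__ = [
    "ResponseSignature",
    "extract_profile",
    "response_signature",
    "group_signature",
]


@dataclass
class ResponseSignature:
    """Per-cell, per-gene treatment-vs-control response values."""

    values: np.ndarray
    cell_id: str
    drug: str
    control: str
    mode: str = "ratio"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise DataError(f"non-finite signature values for cell {self.cell_id}")


def _index(labels: list[str], name: str, axis: str) -> int:
    try:
        return labels.index(name)
    except ValueError:
        raise DataError(f"unknown {axis} label {name!r}") from None


def extract_profile(imputed: ExpressionTensor, drug: str, cell: str) -> np.ndarray:
    """The (drug, :, cell) fiber — one gene-expression vector."""
    d = _index(imputed.drug_labels, drug, "drug")
    c = _index(imputed.cell_labels, cell, "cell")
    return imputed.values[d, :, c].copy()


def response_signature(
    imputed: ExpressionTensor,
    drug: str,
    control_drug: str,
    cell: str,
    pseudocount: float = 1.0,
    mode: str = "ratio",
) -> ResponseSignature:
    """Per-gene response of one cell: treated profile vs its own control profile.

    ratio mode:       x'_m = log2((treat_m + pc) / (control_m + pc))
    difference mode:  x'_m = treat_m - control_m

    The control profile is the same cell's (possibly imputed) control fiber;
    completion is what makes this per-cell contrast well defined, since each
    cell is physically measured under a single drug.
    """
    if mode not in ("ratio", "difference"):
        raise DataError(f"unknown signature mode {mode!r}")
    if pseudocount < 0:
        raise DataError("pseudocount must be >= 0")
    treat = extract_profile(imputed, drug, cell)
    control = extract_profile(imputed, control_drug, cell)
    if mode == "difference":
        values = treat - control
    else:
        # expression is nonnegative; clip model undershoot before the ratio
        num = np.clip(treat, 0.0, None) + pseudocount
        den = np.clip(control, 0.0, None) + pseudocount
        if np.any(den == 0):
            raise NumericError(
                f"zero denominator in log-ratio for cell {cell!r} with pseudocount {pseudocount}"
            )
        values = np.log2(num / den)
    return ResponseSignature(values, cell, drug, control_drug, mode)


def group_signature(
    imputed: ExpressionTensor,
    drug: str,
    control_drug: str,
    cells: list[str],
    pseudocount: float = 1.0,
    mode: str = "ratio",
    label: str | None = None,
) -> ResponseSignature:
    """Signature of a cell group (e.g. one cell type): mean treated profile
    vs mean control profile over the given cells.

    Averaging profiles before the contrast suppresses per-cell imputation
    noise, which matters for group-level enrichment.
    """
    if not cells:
        raise DataError("empty cell group")
    if mode not in ("ratio", "difference"):
        raise DataError(f"unknown signature mode {mode!r}")
    d_t = _index(imputed.drug_labels, drug, "drug")
    d_c = _index(imputed.drug_labels, control_drug, "drug")
    idx = [_index(imputed.cell_labels, c, "cell") for c in cells]
    treat = imputed.values[d_t][:, idx].mean(axis=1)
    control = imputed.values[d_c][:, idx].mean(axis=1)
    if mode == "difference":
        values = treat - control
    else:
        values = np.log2(
            (np.clip(treat, 0.0, None) + pseudocount)
            / (np.clip(control, 0.0, None) + pseudocount)
        )
    return ResponseSignature(values, label or f"group:{len(cells)}cells", drug, control_drug, mode)
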