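"""Unified three-drug treatment-allocation algorithm.

Each subject gets a predicted response probability from the three
finalised models (TNF inhibition / etanercept, IL6-receptor inhibition /
tocilizumab, B-cell depletion / rituximab). The subject is allocated to
the class with the highest probability; if every probability is below the
threshold (default 0.5) the subject is labelled biomarker-negative. Exact
ties are broken by a fixed priority order (TNFi > IL6i > BCD) and flagged
rather than silently resolved.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import VSTMatrix
from .counts import transform_clinical
from .ml import FittedResponseModel

__all__ = ["AllocationResult", "allocate_treatment", "predict_subject", "DRUG_CLASSES"]

#: Drug class labels in tie-break priority order.
DRUG_CLASSES = ("TNF-inhibitor", "IL6-inhibitor", "B-cell depleting agent")

ARM_TO_CLASS = {
    "etanercept": "TNF-inhibitor",
    "tocilizumab": "IL6-inhibitor",
    "rituximab": "B-cell depleting agent",
}


@dataclass
class AllocationResult:
    prob_tnfi: float
    prob_il6i: float
    prob_bcell_depletion: float
    allocation: str  # drug class or "biomarker-negative"
    margin: float  # top1 - top2 probability
    tie: bool = False
    provenance: dict | None = None


def allocate_treatment(
    p_tnfi: float,
    p_il6i: float,
    p_bcd: float,
    threshold: float = 0.5,
) -> AllocationResult:
    """Allocate to the drug class with the highest response probability.

    Subjects with a low predicted probability of response to all three
    classes (all below ``threshold``) are categorised biomarker-negative.
    """
    probs = (float(p_tnfi), float(p_il6i), float(p_bcd))
    for p in probs:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
    top = max(probs)
    ranked = sorted(probs, reverse=True)
    margin = ranked[0] - ranked[1]
    tie = probs.count(top) > 1
    if top < threshold:
        allocation = "biomarker-negative"
    else:
        allocation = DRUG_CLASSES[probs.index(top)]  # first index = priority order
    return AllocationResult(*probs, allocation=allocation, margin=margin, tie=tie)


def predict_subject(
    models: dict[str, FittedResponseModel],
    expression: VSTMatrix | pd.DataFrame,
    clinical_row: pd.Series | pd.DataFrame,
    threshold: float = 0.5,
    transform: bool = True,
) -> AllocationResult:
    """Score one subject with all three models and allocate a therapy.

    ``expression`` is genes x samples on the VST scale (RNA-Seq VST or
    pseudo-RNA-Seq); ``clinical_row`` holds the subject's raw clinical
    covariates (transformed internally unless ``transform=False``). The
    three models are scored independently and combined only through
    :func:`allocate_treatment`.
    """
    expected = {"etanercept", "tocilizumab", "rituximab"}
    if set(models) != expected:
        raise ValueError(f"models must be keyed by arms {sorted(expected)}")
    expr = expression.values if isinstance(expression, VSTMatrix) else expression
    if isinstance(clinical_row, pd.Series):
        clinical_row = clinical_row.to_frame().T
    clin = transform_clinical(clinical_row) if transform else clinical_row
    sample = expr.columns[0] if expr.shape[1] == 1 else None
    if sample is None:
        raise ValueError("predict_subject expects a single-sample expression column")
    features = expr[[sample]].T
    features.index = clin.index
    features = pd.concat([features, clin], axis=1)
    probs = {}
    provenance = {}
    for arm, model in models.items():
        try:
            probs[arm] = float(model.predict_proba(features).iloc[0])
        except KeyError as exc:
            raise KeyError(f"{arm} model: {exc}") from None
        provenance[arm] = {
            "learner": model.learner,
            "n_predictors": len(model.predictors),
            "genes": model.gene_predictors,
            "clinical": model.clinical_predictors,
        }
    result = allocate_treatment(
        probs["etanercept"], probs["tocilizumab"], probs["rituximab"], threshold
    )
    result.provenance = provenance
    return result
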