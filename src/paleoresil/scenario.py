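"""Decision rule classifying the long-term community response pattern.

Three idealized outcomes of a glacial-interglacial perturbation cycle are
distinguished from the three pairwise Bray–Curtis permutation tests
(interglacial-1 vs interglacial-2, glacial vs each interglacial):

* persistent — no comparison departs from the homogeneous-system null: the
  community passed through the cycle unchanged;
* resilient — only the two glacial-interglacial comparisons depart: the
  community shifted to an altered glacial state and then reassembled;
* stochastic — every comparison departs: each interval hosts a unique
  association.

Mixed outcomes (exactly one glacial comparison significant) fit none of the
idealized cells and are labeled indeterminate. Pooled-abundance rank
correlations corroborate but never override the label: under resilience the
interglacial pair should correlate positively and the glacial pairs should
not; a mismatch lowers the confidence flag only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .data_model import ValidationError

LABELS = ("persistent", "resilient", "stochastic", "indeterminate")

DEFAULT_ALPHA = 0.05


@dataclass
class ScenarioCall:
    label: str
    alpha: float
    evidence: dict = field(default_factory=dict)
    confidence: str = "high"  # lowered to "low" on corroboration mismatch

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {
                "label": self.label,
                "alpha": self.alpha,
                "confidence": self.confidence,
                "evidence": self.evidence,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def classify_pattern(
    p_interglacial: float,
    p_glacial_1: float,
    p_glacial_2: float,
    alpha: float = DEFAULT_ALPHA,
    rho_evidence: dict | None = None,
    permanova_p: float | None = None,
) -> ScenarioCall:
    """Map the three pairwise BC-test p-values to a response-pattern label.

    ``p_interglacial`` is the interglacial-interglacial comparison;
    ``p_glacial_1``/``p_glacial_2`` the two glacial-interglacial comparisons.
    ``rho_evidence`` may carry the pooled-abundance Spearman results as
    ``{"rho_interglacial": (rho, p), "rho_glacial_1": (rho, p),
    "rho_glacial_2": (rho, p)}`` and is used only for corroboration.
    """
    ps = (p_interglacial, p_glacial_1, p_glacial_2)
    for p in ps:
        if p is None:
            raise ValidationError("missing p-value in scenario evidence")
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"p-value {p} outside (0, 1]")
    ig_ns = p_interglacial >= alpha
    g1_sig = p_glacial_1 < alpha
    g2_sig = p_glacial_2 < alpha

    if ig_ns and not g1_sig and not g2_sig:
        label = "persistent"
    elif ig_ns and g1_sig and g2_sig:
        label = "resilient"
    elif not ig_ns and g1_sig and g2_sig:
        label = "stochastic"
    else:
        label = "indeterminate"

    evidence = {
        "p_interglacial": p_interglacial,
        "p_glacial_1": p_glacial_1,
        "p_glacial_2": p_glacial_2,
        "alpha": alpha,
    }
    if permanova_p is not None:
        evidence["permanova_p"] = permanova_p

    confidence = "high"
    if rho_evidence is not None:
        evidence["rho_evidence"] = {
            k: {"rho": v[0], "p": v[1]} for k, v in rho_evidence.items()
        }
        if label == "resilient":
            rho_ig, p_rho_ig = rho_evidence.get("rho_interglacial", (None, None))
            ok = rho_ig is not None and rho_ig > 0 and p_rho_ig is not None and p_rho_ig < alpha
            for key in ("rho_glacial_1", "rho_glacial_2"):
                if key in rho_evidence and rho_evidence[key][1] < alpha:
                    ok = False
            if not ok:
                confidence = "low"

    return ScenarioCall(label=label, alpha=alpha, evidence=evidence, confidence=confidence)
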