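"""Retention-time prediction and isoleucine/leucine isoform adjudication.

Isoleucine and leucine are isobaric, so mass spectrometry alone cannot tell
which of the two occupies a given position; chromatography can, because
leucine is slightly more hydrophobic and retains longer on reversed phase.
This module predicts relative retention times with an additive residue
coefficient model and ranks candidate I/L assignments against the observed
shift between an endogenous peak and a spiked synthetic (heavy) reference.

The additive model depends only on residue composition, not order, so
candidates that differ by swapping an I and an L at two positions (equal
composition) are genuinely indistinguishable here; they are returned as a
tied set, to be resolved by a synthetic-standard run.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .peptide_chem import Peptide

__all__ = [
    "RetentionModel",
    "IsoformHypothesis",
    "load_coefficients",
    "default_retention_model",
    "predict_rt",
    "enumerate_il_isoforms",
    "adjudicate_isoforms",
    "tied_leaders",
]

_COEFF_RESOURCE = "guo1986_coefficients.tsv"

# Anchor points for scaling the dimensionless coefficient set to minutes on
# a 70-min gradient: a single I->L substitution in an 8-mer moves the apex
# from 22.3 to 24.2 min on this LC setup.
_ANCHOR_GRADIENT_MIN = 70.0
_ANCHOR_SEQ = "TIKIPAGT"
_ANCHOR_RT = 22.3
_ANCHOR_SWAP_RT = 24.2


@dataclass(frozen=True)
class RetentionModel:
    """Additive retention model: rt = intercept + sum(coefficient[residue]).

    Coefficients are in minutes on the model's gradient scale.  The model is
    compositional: residue order does not affect the prediction (a
    documented limitation, and the reason composition-identical isoform
    candidates tie).
    """

    coefficients: dict[str, float]
    intercept: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.coefficients)
        if missing:
            raise ValueError(f"missing coefficients for residues: {sorted(missing)}")
        if not self.coefficients["L"] > self.coefficients["I"]:
            raise ValueError("retention model must satisfy coefficient(L) > coefficient(I)")


def load_coefficients(path=None) -> dict[str, float]:
    """Read a two-column (residue, coefficient) text table.

    With no path, loads the packaged Guo et al. (1986) pH-2 set.
    Lines starting with '#' are comments.
    """
    if path is None:
        text = (
            resources.files("prmquant").joinpath("data", _COEFF_RESOURCE).read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    coeffs: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, value = line.split()
        coeffs[residue] = float(value)
    return coeffs


def default_retention_model(gradient_minutes: float = 70.0) -> RetentionModel:
    """The packaged coefficient set scaled to minutes.

    The raw coefficients are dimensionless; they are converted to minutes by
    anchoring to the observed retention times of an I/L isoform pair on a
    70-min gradient (one I->L swap = +1.9 min), then scaled linearly for
    other gradient lengths.
    """
    raw = load_coefficients()
    scale = (_ANCHOR_SWAP_RT - _ANCHOR_RT) / (raw["L"] - raw["I"])
    scale *= gradient_minutes / _ANCHOR_GRADIENT_MIN
    anchor_sum = sum(raw[aa] for aa in _ANCHOR_SEQ)
    intercept = _ANCHOR_RT * gradient_minutes / _ANCHOR_GRADIENT_MIN - scale * anchor_sum
    return RetentionModel(
        coefficients={aa: c * scale for aa, c in raw.items()},
        intercept=intercept,
        name=f"guo1986/anchored-{gradient_minutes:g}min",
    )


def predict_rt(p: Peptide, model: RetentionModel) -> float:
    """Predicted retention time in minutes.

    Isotope labels contribute nothing: heavy and light peptidoforms of the
    same sequence co-elute, which is what makes the heavy form usable as an
    in-sample internal standard.
    """
    try:
        return model.intercept + sum(model.coefficients[aa] for aa in p.residues)
    except KeyError as exc:  # pragma: no cover - model invariant guards this
        raise ValueError(f"no retention coefficient for residue {exc}") from exc


def enumerate_il_isoforms(p: Peptide) -> list[Peptide]:
    """All 2^k candidate sequences from toggling each I/L position.

    The input peptide comes first; labels stay at their positions.
    """
    il_positions = [i for i, aa in enumerate(p.residues) if aa in "IL"]
    candidates = [p]
    for mask in range(1, 2 ** len(il_positions)):
        residues = list(p.residues)
        for bit, idx in enumerate(il_positions):
            if mask >> bit & 1:
                residues[idx] = "L" if residues[idx] == "I" else "I"
        candidates.append(Peptide("".join(residues), p.labels))
    return candidates


@dataclass(frozen=True)
class IsoformHypothesis:
    candidate: Peptide
    predicted_rt: float
    predicted_shift: float
    deviation: float
    consistent: bool
    rank: int
    tied: bool


def adjudicate_isoforms(
    observed_shift: float,
    synthetic_reference: Peptide,
    candidates: Iterable[Peptide],
    model: RetentionModel | None = None,
    shift_tolerance: float = 0.5,
) -> list[IsoformHypothesis]:
    """Rank candidate I/L assignments against an observed RT shift.

    ``observed_shift`` is endogenous apex minus synthetic-reference apex in
    minutes.  Each candidate's predicted shift is predict_rt(candidate) −
    predict_rt(reference); candidates are ranked by absolute deviation from
    the observed shift and flagged consistent when within
    ``shift_tolerance``.  Candidates whose deviations agree to numerical
    precision are marked ``tied`` (composition-identical isoforms always
    tie; the tie is reported, never broken arbitrarily).
    """
    if model is None:
        model = default_retention_model()
    candidates = list(candidates)
    if synthetic_reference not in [c.stripped() for c in candidates] and (
        synthetic_reference.stripped() not in [c.stripped() for c in candidates]
    ):
        raise ValueError("synthetic reference must be among the candidates")
    ref_rt = predict_rt(synthetic_reference, model)
    scored = []
    for i, cand in enumerate(candidates):
        rt = predict_rt(cand, model)
        shift = rt - ref_rt
        scored.append((abs(shift - observed_shift), i, cand, rt, shift))
    scored.sort(key=lambda t: (t[0], t[1]))
    out: list[IsoformHypothesis] = []
    for rank, (dev, _, cand, rt, shift) in enumerate(scored, start=1):
        tied = any(
            abs(dev - other[0]) < 1e-9 for other in scored if other[2] is not cand
        )
        out.append(
            IsoformHypothesis(
                candidate=cand,
                predicted_rt=rt,
                predicted_shift=shift,
                deviation=dev,
                consistent=dev <= shift_tolerance,
                rank=rank,
                tied=tied,
            )
        )
    return out


def tied_leaders(hypotheses: Sequence[IsoformHypothesis]) -> list[IsoformHypothesis]:
    """The set of top-ranked hypotheses sharing the best deviation."""
    if not hypotheses:
        return []
    best = hypotheses[0].deviation
    return [h for h in hypotheses if abs(h.deviation - best) < 1e-9]
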