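"""Labelled peptide sequences, monoisotopic masses and PRM inclusion lists.

Sequences are written in a deliberate subset of ProForma v2: the twenty
canonical one-letter residue codes, each optionally followed by a stable
isotope label tag such as ``[Label:13C(6)15N(2)]`` that applies to the
residue immediately preceding it.  A peptide with no label tags is a
"light" peptidoform; the labelled copy is the "heavy" peptidoform used as
both calibrant and internal standard.

Monoisotopic residue, water and proton masses come from pyteomics
(CODATA/NIST values); label mass shifts are computed from the 13C−12C and
15N−14N isotope mass differences.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from pyteomics import mass as _mass

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "C13_SHIFT",
    "N15_SHIFT",
    "IsotopeLabel",
    "Peptide",
    "Ion",
    "PrecursorTarget",
    "parse_sequence",
    "label_mass_shift",
    "monoisotopic_mass",
    "protonated_mass",
    "precursor_mz",
    "fragment_mz",
    "build_inclusion_list",
    "write_inclusion_list",
]

PROTON_MASS: float = _mass.nist_mass["H+"][0][0]
WATER_MASS: float = _mass.calculate_mass(formula="H2O")
C13_SHIFT: float = _mass.nist_mass["C"][13][0] - _mass.nist_mass["C"][12][0]
N15_SHIFT: float = _mass.nist_mass["N"][15][0] - _mass.nist_mass["N"][14][0]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: monoisotopic residue masses, restricted to the canonical alphabet
RESIDUE_MASS: Mapping[str, float] = {
    aa: _mass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES
}


class SequenceError(ValueError):
    """Raised for malformed or unsupported peptide sequence text."""


@dataclass(frozen=True)
class IsotopeLabel:
    """A stable-isotope residue label, e.g. 13C(6)15N(2) for heavy lysine."""

    c13: int = 0
    n15: int = 0

    def __post_init__(self) -> None:
        if self.c13 < 0 or self.n15 < 0:
            raise ValueError("isotope counts must be non-negative")

    def __bool__(self) -> bool:
        return self.c13 > 0 or self.n15 > 0

    @property
    def mass_shift(self) -> float:
        """Mass added to the residue by the label, in Da."""
        return self.c13 * C13_SHIFT + self.n15 * N15_SHIFT

    def to_proforma(self) -> str:
        if not self:
            return ""
        parts = []
        if self.c13:
            parts.append(f"13C({self.c13})")
        if self.n15:
            parts.append(f"15N({self.n15})")
        return "[Label:" + "".join(parts) + "]"


def label_mass_shift(label: IsotopeLabel) -> float:
    """Mass shift of an isotope label in Da (0 for the empty label)."""
    return label.mass_shift


@dataclass(frozen=True)
class Peptide:
    """A peptidoform: residue string plus positional isotope labels.

    ``labels`` maps 1-based residue positions to :class:`IsotopeLabel`;
    internally it is stored as a sorted tuple so peptides are hashable and
    comparable by value.
    """

    residues: str
    labels: tuple[tuple[int, IsotopeLabel], ...] = ()
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("empty peptide sequence")
        bad = set(self.residues) - set(CANONICAL_RESIDUES)
        if bad:
            raise SequenceError(f"unknown residue letter(s): {sorted(bad)}")
        labels = tuple(sorted((int(p), l) for p, l in dict(self.labels).items() if l))
        object.__setattr__(self, "labels", labels)
        for pos, _ in labels:
            if not 1 <= pos <= len(self.residues):
                raise SequenceError(
                    f"label position {pos} outside 1..{len(self.residues)}"
                )
        if not self.display_name:
            object.__setattr__(self, "display_name", self.to_proforma())

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def label_map(self) -> dict[int, IsotopeLabel]:
        return dict(self.labels)

    @property
    def is_heavy(self) -> bool:
        return bool(self.labels)

    @property
    def label_type(self) -> str:
        return "heavy" if self.is_heavy else "light"

    def to_proforma(self) -> str:
        """Canonical ProForma-subset text; parse_sequence round-trips it."""
        lmap = self.label_map
        out = []
        for i, aa in enumerate(self.residues, start=1):
            out.append(aa)
            if i in lmap:
                out.append(lmap[i].to_proforma())
        return "".join(out)

    def stripped(self) -> "Peptide":
        """The light peptidoform with the same sequence."""
        return Peptide(self.residues)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_proforma()


_LABEL_RE = re.compile(r"\[Label:(?:13C\((\d+)\))?(?:15N\((\d+)\))?\]")
_TOKEN_RE = re.compile(r"([A-Za-z])|(\[[^\]]*\])")


def parse_sequence(text: str) -> Peptide:
    """Parse a ProForma-subset string into a :class:`Peptide`.

    Supported grammar: canonical residues, each optionally followed by one
    ``[Label:13C(x)15N(y)]`` tag that attaches to the preceding residue.
    """
    if not text:
        raise SequenceError("empty peptide sequence")
    residues: list[str] = []
    labels: dict[int, IsotopeLabel] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise SequenceError(f"unexpected character at offset {pos}: {text[pos]!r}")
        if m.group(1):
            aa = m.group(1)
            if aa not in CANONICAL_RESIDUES:
                raise SequenceError(f"unknown residue letter: {aa!r}")
            residues.append(aa)
        else:
            lm = _LABEL_RE.fullmatch(m.group(2))
            if lm is None or (lm.group(1) is None and lm.group(2) is None):
                raise SequenceError(f"malformed label tag: {m.group(2)!r}")
            if not residues:
                raise SequenceError("label tag before any residue")
            idx = len(residues)
            if idx in labels:
                raise SequenceError(f"duplicate label at position {idx}")
            labels[idx] = IsotopeLabel(
                c13=int(lm.group(1) or 0), n15=int(lm.group(2) or 0)
            )
        pos = m.end()
    return Peptide("".join(residues), tuple(labels.items()))


def monoisotopic_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass in Da, including isotope-label shifts."""
    total = WATER_MASS + sum(RESIDUE_MASS[aa] for aa in p.residues)
    total += sum(label.mass_shift for _, label in p.labels)
    return total


def protonated_mass(p: Peptide) -> float:
    """Singly protonated monoisotopic mass [M+H]+ in Da."""
    return monoisotopic_mass(p) + PROTON_MASS


def precursor_mz(p: Peptide, z: int = 1) -> float:
    """Precursor m/z at charge ``z`` (positive mode)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (monoisotopic_mass(p) + z * PROTON_MASS) / z


@dataclass(frozen=True)
class Ion:
    """A b- or y-series fragment ion."""

    series: str
    ordinal: int
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"series must be 'b' or 'y', got {self.series!r}")
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


def fragment_mz(p: Peptide, series: str, ordinal: int, z: int = 1) -> Ion:
    """b/y fragment ion of ``p``; labels count only when their residue is in
    the fragment (b_k covers positions 1..k, y_k covers the last k)."""
    n = len(p)
    if not 1 <= ordinal <= n - 1:
        raise ValueError(f"ordinal must be in 1..{n - 1}, got {ordinal}")
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    lmap = p.label_map
    if series == "b":
        positions = range(1, ordinal + 1)
        neutral = sum(RESIDUE_MASS[p.residues[i - 1]] for i in positions)
    elif series == "y":
        positions = range(n - ordinal + 1, n + 1)
        neutral = WATER_MASS + sum(RESIDUE_MASS[p.residues[i - 1]] for i in positions)
    else:
        raise ValueError(f"series must be 'b' or 'y', got {series!r}")
    neutral += sum(lmap[i].mass_shift for i in positions if i in lmap)
    return Ion(series=series, ordinal=ordinal, charge=z, mz=(neutral + z * PROTON_MASS) / z)


@dataclass(frozen=True)
class PrecursorTarget:
    """One inclusion-list entry for a PRM acquisition."""

    peptide: Peptide
    mz: float
    charge: int
    polarity: str = "Positive"
    rt_window: Optional[tuple[float, float]] = None
    label_type: str = "light"

    def __post_init__(self) -> None:
        if self.rt_window is not None and not self.rt_window[0] < self.rt_window[1]:
            raise ValueError("rt_window start must be < end")
        expected = precursor_mz(self.peptide, self.charge)
        if abs(self.mz - expected) > 1e-6:
            raise ValueError(
                f"mz {self.mz} inconsistent with peptide/charge ({expected:.4f})"
            )


def build_inclusion_list(
    peptides: Iterable[Peptide],
    z: int = 1,
    rt_windows: Optional[Mapping[str, tuple[float, float]]] = None,
) -> list[PrecursorTarget]:
    """One target per peptidoform, sorted by m/z.

    ``rt_windows`` maps canonical ProForma text (or the bare residue string,
    matched as a fallback) to a (start, end) minute window.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("peptide set is empty")
    seen: set[Peptide] = set()
    targets = []
    for p in peptides:
        if p in seen:
            raise ValueError(f"duplicate peptidoform: {p.to_proforma()}")
        seen.add(p)
        window = None
        if rt_windows:
            window = rt_windows.get(p.to_proforma()) or rt_windows.get(p.residues)
        targets.append(
            PrecursorTarget(
                peptide=p,
                mz=precursor_mz(p, z),
                charge=z,
                rt_window=tuple(window) if window else None,
                label_type=p.label_type,
            )
        )
    return sorted(targets, key=lambda t: t.mz)


INCLUSION_LIST_COLUMNS = [
    "Mass [m/z]",
    "Formula",
    "Species",
    "CS [z]",
    "Polarity",
    "Start [min]",
    "End [min]",
    "Comment",
]


def write_inclusion_list(targets: Sequence[PrecursorTarget], path) -> None:
    """Write a Q Exactive-style inclusion-list CSV.

    The Comment column carries the canonical ProForma text so the list
    round-trips the peptidoform identity.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(INCLUSION_LIST_COLUMNS)
        for t in targets:
            start, end = ("", "") if t.rt_window is None else t.rt_window
            writer.writerow(
                [f"{t.mz:.4f}", "", "", t.charge, t.polarity, start, end,
                 t.peptide.to_proforma()]
            )
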