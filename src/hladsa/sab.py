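"""Single-antigen bead (SAB) assay model.

Each bead carries one class I allele or one class II beta-alpha heterodimer
(DQ/DP) or beta chain (DRB).  Reactivity is read as normalized mean
fluorescence intensity (MFI).  A bead is called positive when its MFI
exceeds 500 *and* exceeds five times the lowest-MFI bead of the same class
in the same sample run; positive beads sharing a beta chain merge into one
antibody specificity accumulating the reactive alpha variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import AssayError
from .hla import ALPHA_PARTNER, CLASS_I_LOCI, Allele, parse_allele

#: default positivity rule: MFI > 500 and MFI / lowest-bead MFI > 5
MFI_THRESHOLD = 500.0
MFI_RATIO = 5.0

_BETA_LOCI_II = frozenset({"DRB1", "DRB3", "DRB4", "DRB5", "DQB1", "DPB1"})


@dataclass(frozen=True, order=True)
class BeadTarget:
    """The HLA molecule on one bead: class I allele, or class II beta(+alpha)."""

    beta: Allele
    alpha: Allele | None = None

    def __post_init__(self) -> None:
        if self.beta.locus in CLASS_I_LOCI:
            if self.alpha is not None:
                raise AssayError(f"class I target {self.beta} cannot carry an alpha chain")
        elif self.beta.locus in _BETA_LOCI_II:
            if self.alpha is not None:
                want = ALPHA_PARTNER.get(self.beta.locus)
                if want is None or self.alpha.locus != want:
                    raise AssayError(
                        f"alpha chain {self.alpha} does not pair with {self.beta}"
                    )
        else:
            raise AssayError(f"{self.beta.locus} is not a valid bead target locus")

    @property
    def hla_class(self) -> str:
        return self.beta.hla_class

    def __str__(self) -> str:
        if self.alpha is None:
            return str(self.beta)
        return f"{self.beta}/{self.alpha}"


def parse_target(text: str) -> BeadTarget:
    """Parse ``"A*11:01"`` or ``"DQB1*03:02/DQA1*02:01"`` target strings."""
    parts = [p.strip() for p in text.strip().split("/")]
    if len(parts) == 1:
        return BeadTarget(parse_allele(parts[0]))
    if len(parts) == 2:
        return BeadTarget(parse_allele(parts[0]), parse_allele(parts[1]))
    raise AssayError(f"malformed bead target {text!r}")


@dataclass(frozen=True)
class BeadResult:
    sample_id: str
    target: BeadTarget
    mfi: float

    def __post_init__(self) -> None:
        if self.mfi < 0 or math.isnan(self.mfi):
            raise AssayError(f"negative or undefined MFI {self.mfi} on {self.target}")


class PanelDefinition:
    """The set of HLA molecules represented on the assay.

    Membership is exact at the two-field (and alpha, when present) level:
    a donor allele or heterodimer absent from the panel cannot be assessed
    by the assay at all.
    """

    def __init__(self, targets: Iterable[BeadTarget]) -> None:
        self.targets = frozenset(targets)
        self._betas = frozenset(t.beta for t in self.targets)

    @classmethod
    def from_csv(cls, path) -> "PanelDefinition":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        col = "target" if "target" in df.columns else df.columns[0]
        return cls(parse_target(s) for s in df[col] if s)

    def __contains__(self, target: BeadTarget) -> bool:
        return target in self.targets

    def has_allele(self, allele: Allele) -> bool:
        """True when some bead carries this class I allele / beta chain."""
        return allele in self._betas

    def has_heterodimer(self, beta: Allele, alpha: Allele) -> bool:
        return BeadTarget(beta, alpha) in self.targets

    def __len__(self) -> int:
        return len(self.targets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"target": sorted(str(t) for t in self.targets)}
        )


def call_positive(beads: Sequence[BeadResult],
                  mfi_threshold: float = MFI_THRESHOLD,
                  mfi_ratio: float = MFI_RATIO) -> list[BeadResult]:
    """Apply the positivity rule to one sample's beads of one class.

    A bead is positive iff ``mfi > mfi_threshold`` and
    ``mfi / min(mfi)`` over the run ``> mfi_ratio``.  A zero lowest bead
    makes the ratio +infinity, so the MFI threshold alone decides.
    """
    if not beads:
        raise AssayError("cannot call positivity on an empty bead list")
    samples = {b.sample_id for b in beads}
    classes = {b.target.hla_class for b in beads}
    if len(samples) > 1 or len(classes) > 1:
        raise AssayError(
            f"positivity is called per sample and class; got samples {samples}, "
            f"classes {classes}"
        )
    lowest = min(b.mfi for b in beads)
    positive = []
    for b in beads:
        ratio = b.mfi / lowest if lowest > 0 else math.inf
        if b.mfi > mfi_threshold and ratio > mfi_ratio:
            positive.append(b)
    return positive


def call_positive_frame(df: pd.DataFrame,
                        mfi_threshold: float = MFI_THRESHOLD,
                        mfi_ratio: float = MFI_RATIO) -> pd.DataFrame:
    """Vectorized positivity call over a bead table.

    ``df`` needs columns sample_id, hla_class, mfi (plus anything else,
    carried through).  Returns the positive rows.
    """
    lowest = df.groupby(["sample_id", "hla_class"])["mfi"].transform("min")
    ratio_ok = (df["mfi"] > mfi_ratio * lowest) | (lowest <= 0)
    return df[(df["mfi"] > mfi_threshold) & ratio_ok]


@dataclass(frozen=True)
class Specificity:
    """One antibody specificity: a bead group sharing a target molecule."""

    sample_id: str
    locus: str
    beta_alleles: tuple[Allele, ...]
    alpha_alleles: tuple[Allele, ...] = ()
    mfi_min: float = 0.0
    mfi_max: float = 0.0

    def __post_init__(self) -> None:
        if not self.beta_alleles:
            raise AssayError("a specificity needs at least one member allele")
        if any(a.locus != self.locus for a in self.beta_alleles):
            raise AssayError(
                f"mixed-locus specificity: {self.beta_alleles} under {self.locus}"
            )

    @property
    def hla_class(self) -> str:
        return self.beta_alleles[0].hla_class

    def __str__(self) -> str:
        betas = ";".join(str(a) for a in self.beta_alleles)
        if self.alpha_alleles:
            return f"{betas}/{';'.join(str(a) for a in self.alpha_alleles)}"
        return betas


def group_specificities(positive: Sequence[BeadResult],
                        cross_reactive_groups: Sequence[frozenset[Allele]] = ()
                        ) -> list[Specificity]:
    """Partition positive beads into antibody specificities.

    DQ/DP beads sharing a beta chain merge into one specificity that
    accumulates the reactive alpha variants.  Class I and DRB beads stay
    one specificity per allele unless an explicit cross-reactive allele
    group covers them.
    """
    by_key: dict[tuple, list[BeadResult]] = {}
    for b in positive:
        beta = b.target.beta
        if b.target.alpha is not None or beta.locus in ALPHA_PARTNER:
            key = (b.sample_id, "beta", beta)
        else:
            group = next(
                (i for i, g in enumerate(cross_reactive_groups) if beta in g),
                None,
            )
            key = ((b.sample_id, "crg", group) if group is not None
                   else (b.sample_id, "single", beta))
        by_key.setdefault(key, []).append(b)
    out = []
    for members in by_key.values():
        betas: list[Allele] = []
        alphas: list[Allele] = []
        for b in members:
            if b.target.beta not in betas:
                betas.append(b.target.beta)
            if b.target.alpha is not None and b.target.alpha not in alphas:
                alphas.append(b.target.alpha)
        mfis = [b.mfi for b in members]
        out.append(Specificity(
            sample_id=members[0].sample_id,
            locus=betas[0].locus,
            beta_alleles=tuple(sorted(betas)),
            alpha_alleles=tuple(sorted(alphas)),
            mfi_min=min(mfis),
            mfi_max=max(mfis),
        ))
    out.sort(key=lambda s: (s.sample_id, s.locus, str(s)))
    return out


def read_bead_csv(path) -> list[BeadResult]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    return [
        BeadResult(str(r.sample_id), parse_target(r.target), float(r.mfi))
        for r in df.itertuples(index=False)
    ]
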