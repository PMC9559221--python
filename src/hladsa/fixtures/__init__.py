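"""Bundled worked reference cohort: 39 post-transplant antibody workups.

The bundle encodes *inputs only*: per-patient antibody bead-group rows
with MFI values or ranges, the low-resolution donor typing view
(including frequency-estimated C/DQ entries and loci marked unavailable),
the complete high-resolution donor typing, and the single-antigen-bead
panel availability (donor alleles known to be unrepresented on the assay
are absent from the panel file).  Verdicts and patient groups are never
encoded; they are outputs under test.

``registry_synthetic.csv`` is a synthetic eplet registry constructed so
that every non-shared-eplet annotation in the worked cohort holds under
the package's set algebra; it is not any real HLAMatchmaker release.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ..eplets import EpletRegistry
from ..errors import FixtureError
from ..hla import Genotype, parse_allele, read_typing_table
from ..sab import PanelDefinition, Specificity

N_PATIENTS = 39


def _path(name: str):
    return resources.files(__package__).joinpath(name)


@dataclass
class FixtureBundle:
    """Validated worked-cohort inputs, keyed by patient id '1'..'39'."""

    specs_by_patient: dict[str, list[Specificity]]
    donors_lr: dict[str, Genotype]
    donors_hr: dict[str, Genotype]
    panel: PanelDefinition

    @property
    def patients(self) -> list[str]:
        return sorted(self.specs_by_patient, key=int)


def _parse_spec_row(row, line_no: int) -> Specificity:
    try:
        betas = tuple(parse_allele(s) for s in row.beta_alleles.split(";"))
        alphas = tuple(parse_allele(s) for s in row.alpha_alleles.split(";")
                       ) if row.alpha_alleles else ()
        return Specificity(
            sample_id=str(row.patient_id),
            locus=betas[0].locus,
            beta_alleles=betas,
            alpha_alleles=alphas,
            mfi_min=float(row.mfi_min),
            mfi_max=float(row.mfi_max),
        )
    except Exception as exc:
        raise FixtureError(f"specificity table row {line_no}: {exc}") from exc


def load_fixture() -> FixtureBundle:
    """Load and validate the bundled worked-cohort tables."""
    specs_df = pd.read_csv(_path("table3_specs.csv"), dtype=str,
                           keep_default_na=False)
    specs: dict[str, list[Specificity]] = {}
    for i, row in enumerate(specs_df.itertuples(index=False), start=2):
        specs.setdefault(str(row.patient_id), []).append(_parse_spec_row(row, i))
    with resources.as_file(_path("table3_lr.tsv")) as p:
        donors_lr = read_typing_table(p)
    with resources.as_file(_path("table3_hr.tsv")) as p:
        donors_hr = read_typing_table(p)
    with resources.as_file(_path("table3_panel.csv")) as p:
        panel = PanelDefinition.from_csv(p)

    if len(specs) != N_PATIENTS:
        raise FixtureError(
            f"expected {N_PATIENTS} patients, found {len(specs)}"
        )
    for pid, spec_list in specs.items():
        for s in spec_list:
            donor = donors_hr.get(pid)
            if donor is None or not donor.available(s.locus):
                raise FixtureError(
                    f"patient {pid}: no HR donor typing at {s.locus}"
                )
        if pid not in donors_lr:
            raise FixtureError(f"patient {pid}: no LR donor typing")
    return FixtureBundle(specs, donors_lr, donors_hr, panel)


def load_registry() -> EpletRegistry:
    """The bundled synthetic eplet registry."""
    with resources.as_file(_path("registry_synthetic.csv")) as p:
        return EpletRegistry.from_csv(p)
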