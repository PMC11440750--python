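"""Joint dataset container passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pedigree import Pedigree
from .popstruct import GenotypeSet


@dataclass
class Dataset:
    """Pedigree + phenotypes + (optional) genotypes + breed labels.

    ``phenotypes`` has one row per recorded animal: ``id``, one column per
    trait (NaN = unrecorded) and a contemporary-group code ``cg``
    (flock x year).  ``breed_labels`` maps genotyped animal id -> label
    (e.g. M/C/D) for scenario construction.
    """

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    genotypes: GenotypeSet | None = None
    breed_labels: pd.Series | None = None
    traits: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if "id" not in self.phenotypes.columns or "cg" not in self.phenotypes.columns:
            raise ValidationError("phenotype table needs 'id' and 'cg' columns")
        if not self.traits:
            self.traits = [c for c in self.phenotypes.columns if c not in ("id", "cg")]
        known = set(int(a) for a in self.pedigree.ids)
        bad = [a for a in self.phenotypes["id"] if int(a) not in known]
        if bad:
            raise ValidationError(f"phenotyped animals missing from pedigree: {bad[:5]}")
        if self.genotypes is not None:
            badg = [a for a in self.genotypes.animal_ids if int(a) not in known]
            if badg:
                raise ValidationError(f"genotyped animals missing from pedigree: {badg[:5]}")

    def copy_with(self, phenotypes=None, genotypes=None) -> "Dataset":
        return Dataset(
            self.pedigree,
            self.phenotypes if phenotypes is None else phenotypes,
            self.genotypes if genotypes is None else genotypes,
            self.breed_labels,
            list(self.traits),
        )

    @property
    def genotyped_ids(self) -> np.ndarray:
        return self.genotypes.animal_ids if self.genotypes is not None else np.array([], dtype=int)
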