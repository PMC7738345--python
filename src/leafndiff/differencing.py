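"""Standard-field selection and the reflectance / N-content difference set.

The treatment with the highest grain yield defines the "standard field".
Its mean spectrum and mean leaf N content are the reference; every sample
from a non-standard plot is expressed as a signed difference against that
reference (negative ΔN = nitrogen deficit relative to the max-yield
standard).  The difference set, split into training and validation
portions, is the input to every reduction and inverse model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grid import N_BANDS
from .simulate import reflectance_matrix

__all__ = [
    "StandardReference",
    "DifferenceSet",
    "select_standard",
    "build_reference",
    "compute_differences",
    "split_train_validation",
]

TRAIN = "train"
VALIDATION = "val"


@dataclass(frozen=True)
class StandardReference:
    """Reference spectrum and N content of the max-yield treatment."""

    standard_treatment: int
    standard_spectrum: np.ndarray  # (600,), mean reflectance, in [0, 1]
    standard_n: float  # mg/g

    def __post_init__(self) -> None:
        spec = np.asarray(self.standard_spectrum, dtype=float)
        if spec.shape != (N_BANDS,):
            raise ValueError(f"standard spectrum must have {N_BANDS} bands")
        if self.standard_n <= 0:
            raise ValueError("standard N content must be positive")
        object.__setattr__(self, "standard_spectrum", spec)


@dataclass(frozen=True)
class DifferenceSet:
    """Signed differences of non-standard samples against the reference.

    ``delta_r`` is (n, 600): reflectance minus the standard spectrum;
    ``delta_n`` (mg/g) is N content minus the standard N.  ``split`` is
    None before partitioning, afterwards an array of "train"/"val" labels
    aligned with the rows.
    """

    delta_r: np.ndarray
    delta_n: np.ndarray
    sample_ids: tuple[str, ...]
    reference: StandardReference
    split: np.ndarray | None = None

    def __post_init__(self) -> None:
        dr = np.asarray(self.delta_r, dtype=float)
        dn = np.asarray(self.delta_n, dtype=float)
        if dr.ndim != 2 or dr.shape[1] != N_BANDS:
            raise ValueError(f"delta_r must be (n, {N_BANDS})")
        if dn.shape != (dr.shape[0],):
            raise ValueError("delta_n must align with delta_r rows")
        if len(self.sample_ids) != dr.shape[0]:
            raise ValueError("sample_ids must align with rows")
        if self.split is not None:
            s = np.asarray(self.split)
            if s.shape != (dr.shape[0],):
                raise ValueError("split labels must align with rows")
            if not set(np.unique(s)) <= {TRAIN, VALIDATION}:
                raise ValueError("split labels must be 'train' or 'val'")
            object.__setattr__(self, "split", s)
        object.__setattr__(self, "delta_r", dr)
        object.__setattr__(self, "delta_n", dn)

    def __len__(self) -> int:
        return self.delta_r.shape[0]

    def _mask(self, label: str) -> np.ndarray:
        if self.split is None:
            raise ValueError("difference set has not been split yet")
        return self.split == label

    @property
    def train_mask(self) -> np.ndarray:
        return self._mask(TRAIN)

    @property
    def validation_mask(self) -> np.ndarray:
        return self._mask(VALIDATION)


def select_standard(yields: pd.DataFrame) -> int:
    """Return the treatment (kg/ha) with strictly maximal yield.

    Raises on an exact tie at the maximum: the max-yield rule is then
    undefined and the caller must decide.
    """
    if len(yields) == 0:
        raise ValueError("empty yield table")
    y = yields["yield"].to_numpy(dtype=float)
    top = np.max(y)
    winners = yields.loc[y == top, "treatment"].tolist()
    if len(winners) > 1:
        raise ValueError(f"tie in maximal yield between treatments {winners}")
    return int(winners[0])


def build_reference(samples: pd.DataFrame,
                    standard_treatment: int) -> StandardReference:
    """Mean spectrum and mean N content over the standard-treatment samples."""
    std = samples[samples["treatment"] == standard_treatment]
    if len(std) == 0:
        raise ValueError(f"no samples with treatment {standard_treatment}")
    spectrum = reflectance_matrix(std).mean(axis=0)
    return StandardReference(
        standard_treatment=int(standard_treatment),
        standard_spectrum=spectrum,
        standard_n=float(std["n_content"].mean()),
    )


def compute_differences(samples: pd.DataFrame,
                        reference: StandardReference) -> DifferenceSet:
    """Signed ΔR and ΔN for every non-standard sample.

    Standard-treatment samples are excluded: their differences cluster at
    zero by construction and carry no deficiency information.
    """
    refl = reflectance_matrix(samples)
    if refl.shape[1] != reference.standard_spectrum.shape[0]:
        raise ValueError("sample grid does not match the reference grid")
    non_std = samples["treatment"] != reference.standard_treatment
    sub = samples[non_std]
    delta_r = reflectance_matrix(sub) - reference.standard_spectrum
    delta_n = sub["n_content"].to_numpy(dtype=float) - reference.standard_n
    return DifferenceSet(
        delta_r=delta_r,
        delta_n=delta_n,
        sample_ids=tuple(sub["sample_id"]),
        reference=reference,
    )


def split_train_validation(diffs: DifferenceSet,
                           fraction: float = 0.73,
                           seed: int = 0) -> DifferenceSet:
    """Random uniform train/validation partition with round(n*fraction) train.

    Unstratified: only the partition sizes are constrained (259 samples at
    fraction 0.73 give the 189/70 split of the original protocol).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.full(n, VALIDATION, dtype=object)
    labels[order[:n_train]] = TRAIN
    return replace(diffs, split=labels)
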