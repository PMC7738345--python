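"""CSV persistence for the pipeline's tables.

Sample tables carry reflectance columns R401..R1000; difference sets carry
D401..D1000 plus the ΔN column and the split label; the standard reference
is a small sidecar with one row per band plus the standard N content.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differencing import DifferenceSet, StandardReference
from .features import FeatureSet
from .grid import DIFFERENCE_COLUMNS, N_BANDS, wavelengths


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_yields(yields: pd.DataFrame, path) -> None:
    yields.to_csv(path, index=False)


def read_yields(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_reference(reference: StandardReference, path) -> None:
    df = pd.DataFrame({
        "wavelength_nm": wavelengths().astype(int),
        "standard_reflectance": reference.standard_spectrum,
    })
    df["standard_treatment"] = reference.standard_treatment
    df["standard_n"] = reference.standard_n
    df.to_csv(path, index=False)


def read_reference(path) -> StandardReference:
    df = pd.read_csv(path)
    return StandardReference(
        standard_treatment=int(df["standard_treatment"].iloc[0]),
        standard_spectrum=df["standard_reflectance"].to_numpy(dtype=float),
        standard_n=float(df["standard_n"].iloc[0]),
    )


def write_difference_set(diffs: DifferenceSet, path) -> None:
    df = pd.DataFrame(diffs.delta_r, columns=DIFFERENCE_COLUMNS)
    df.insert(0, "sample_id", list(diffs.sample_ids))
    df.insert(1, "delta_n", diffs.delta_n)
    df.insert(2, "split", diffs.split if diffs.split is not None else "")
    df.to_csv(path, index=False)


def read_difference_set(path, reference: StandardReference) -> DifferenceSet:
    df = pd.read_csv(path, keep_default_na=False)
    split = df["split"].to_numpy(dtype=object)
    if (split == "").all():
        split = None
    return DifferenceSet(
        delta_r=df[DIFFERENCE_COLUMNS].to_numpy(dtype=float),
        delta_n=df["delta_n"].to_numpy(dtype=float),
        sample_ids=tuple(df["sample_id"]),
        reference=reference,
        split=split,
    )


def write_features(feats: FeatureSet, path) -> None:
    cols = [f"A{i + 1}" for i in range(feats.n_features)]
    df = pd.DataFrame(feats.X, columns=cols)
    df.insert(0, "sample_id", list(feats.sample_ids))
    df.insert(1, "split", feats.split if feats.split is not None else "")
    df.insert(2, "method", feats.method)
    df.to_csv(path, index=False)


def read_features(path) -> FeatureSet:
    df = pd.read_csv(path, keep_default_na=False)
    cols = [c for c in df.columns if c.startswith("A")]
    split = df["split"].to_numpy(dtype=object)
    if (split == "").all():
        split = None
    return FeatureSet(
        X=df[cols].to_numpy(dtype=float),
        sample_ids=tuple(df["sample_id"]),
        method=str(df["method"].iloc[0]),
        split=split,
    )


def write_reports(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)
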