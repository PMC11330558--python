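"""Trait-table and curve CSV I/O with validation."""

from __future__ import annotations

import numpy as np
import pandas as pd

HABITATS = ("marine", "marginal", "continental")

TRAIT_COLUMNS = ("taxon", "max_length_cm", "log_size", "habitat",
                 "palaeolatitude_deg", "clade", "suborder")


def read_trait_table(path) -> pd.DataFrame:
    """Read and validate a trait CSV (taxon, max body length, habitat, ...).

    ``log_size`` is recomputed as the natural log of ``max_length_cm`` if
    absent, and checked for consistency if present.
    """
    df = pd.read_csv(path)
    missing = {"taxon", "max_length_cm", "habitat"} - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if df["taxon"].duplicated().any():
        dup = df.loc[df["taxon"].duplicated(), "taxon"].tolist()
        raise ValueError(f"duplicate taxa in trait table: {dup}")
    if (df["max_length_cm"] <= 0).any():
        bad = df.loc[df["max_length_cm"] <= 0, "taxon"].tolist()
        raise ValueError(f"non-positive body lengths for: {bad}")
    if "log_size" in df.columns:
        if not np.allclose(df["log_size"], np.log(df["max_length_cm"]), atol=1e-9):
            raise ValueError("log_size column inconsistent with ln(max_length_cm)")
    else:
        df["log_size"] = np.log(df["max_length_cm"])
    bad_hab = set(df["habitat"].dropna()) - set(HABITATS)
    if bad_hab:
        raise ValueError(f"habitat states outside {HABITATS}: {sorted(bad_hab)}")
    if "palaeolatitude_deg" in df.columns:
        lat = df["palaeolatitude_deg"].dropna()
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("palaeolatitude outside [-90, 90]")
    return df


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
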