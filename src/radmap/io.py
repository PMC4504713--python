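"""Small tabular formats shared by the pipeline stages."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def read_phenotypes(path: str | Path) -> pd.Series:
    """Phenotype TSV (line id, value) -> Series indexed by line id."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (line, value)")
    df.columns = ["line", "value", *df.columns[2:]]
    return pd.Series(df.value.to_numpy(dtype=float), index=df.line, name="value")


def write_phenotypes(pheno: pd.DataFrame | pd.Series, path: str | Path) -> None:
    if isinstance(pheno, pd.Series):
        pheno = pheno.rename("value").rename_axis("line").reset_index()
    pheno.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_lod_profile(profile: pd.DataFrame, path: str | Path) -> None:
    cols = ["group", "pos_cM", "lod", "effect", "pve"]
    out = profile[cols].copy()
    out["pos_cM"] = out.pos_cM.map(lambda v: f"{v:.3f}")
    for c in ("lod", "effect", "pve"):
        out[c] = out[c].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_lod_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"group": str})


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
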