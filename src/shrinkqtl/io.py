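"""CSV readers/writers and run manifests.

Interchange formats are plain UTF-8 CSV with a header row:

* map file: ``locus,chromosome,position_cM`` (optional ``is_pseudomarker``);
* genotype file: rows = individuals, columns = marker loci; values are state
  labels (e.g. ``A1A1``), coded numbers, or probability-derived scores;
  missing calls are ``-`` or empty;
* phenotype file: single ``phenotype`` column (or a single unnamed column).
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genmap import GeneticMap, calls_from_labels, code_genotypes, get_design

__all__ = ["read_cross", "write_results", "write_manifest"]

_MISSING_TOKENS = ("-", "", "NA", "nan", "NaN")


def read_cross(genotype_csv, map_csv, phenotype_csv, cross,
               impute_phenotype_mean: bool = False):
    """Read and validate a mapping dataset.

    Genotype columns must match the map's marker loci (pseudomarker columns
    may be absent). Label-valued genotypes are converted to coded scores via
    the design's coding rule; numeric columns (including probability-derived
    scores) pass through unchanged. Returns ``(gmap, X, y)`` where X covers
    all map loci with NaN at loci lacking data.

    Missing phenotypes are NaN; with ``impute_phenotype_mean`` they are
    replaced by the sample mean.
    """
    cross = get_design(cross)
    gmap = GeneticMap.from_csv(map_csv)
    geno = pd.read_csv(genotype_csv, dtype=str, keep_default_na=False)
    unknown = [c for c in geno.columns if c not in set(gmap.loci)]
    if unknown:
        raise ValueError(
            f"genotype columns not on the map: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
    n = len(geno)
    X = np.full((n, gmap.n_loci), np.nan)
    for j, locus in enumerate(gmap.loci):
        if locus not in geno.columns:
            continue
        col = geno[locus].str.strip()
        numeric = pd.to_numeric(col.replace(list(_MISSING_TOKENS), np.nan), errors="coerce")
        non_missing = ~col.isin(_MISSING_TOKENS)
        if numeric[non_missing].notna().all():
            X[:, j] = numeric.to_numpy()
        else:
            calls = calls_from_labels(col.to_numpy(), cross, missing=_MISSING_TOKENS)
            coded = code_genotypes(np.where(calls < 0, 0, calls)[:, None], cross)
            coded = coded[:, 0].astype(float)
            coded[calls < 0] = np.nan
            X[:, j] = coded

    pheno = pd.read_csv(phenotype_csv)
    col = pheno.columns[0] if "phenotype" not in pheno.columns else "phenotype"
    y = pd.to_numeric(pheno[col], errors="coerce").to_numpy(dtype=float)
    if len(y) != n:
        raise ValueError(
            f"{n} genotyped individuals but {len(y)} phenotypes"
        )
    if impute_phenotype_mean and np.isnan(y).any():
        y[np.isnan(y)] = np.nanmean(y)
    return gmap, X, y


def write_results(out_dir, effects=None, thresholds=None, calls=None, pe=None):
    """Write tidy result tables (effects/thresholds/calls/pe CSVs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, obj in (
        ("effects", effects), ("thresholds", thresholds),
        ("calls", calls), ("pe", pe),
    ):
        if obj is None:
            continue
        df = obj if isinstance(obj, pd.DataFrame) else obj.to_frame()
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = str(path)
    return written


def _digest(path) -> str:
    hsh = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            hsh.update(chunk)
    return hsh.hexdigest()


def write_manifest(out_dir, command: str, config: dict, seeds: dict,
                   input_files=()) -> Path:
    """Record command, configuration, seeds and input digests for a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): _digest(p) for p in input_files},
        "software": {"shrinkqtl": __version__, "python": platform.python_version()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
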