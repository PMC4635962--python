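"""On-disk formats: gzip/plain TSV for genotypes, marker maps and phenotypes,
JSON for truth objects, fit results and QC reports, and an optional importer
for RData genotype/phenotype deposits."""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from crossvar.simulate import GenotypeMatrix, MarkerMap, PhenotypeTable

__all__ = [
    "write_marker_map",
    "read_marker_map",
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_json",
    "import_rdata",
]


def write_marker_map(mmap: MarkerMap, path) -> None:
    mmap.to_frame().to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    return MarkerMap(df["chrom"].to_numpy(), df["pos_bp"].to_numpy())


def write_genotypes(G: GenotypeMatrix, path) -> None:
    """Genotypes as (gzip) TSV, rows = segregants, columns = markers."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        header = "\t".join(f"m{i:05d}" for i in range(G.n_markers))
        fh.write(header + "\n")
        np.savetxt(fh, G.values, fmt="%d", delimiter="\t")


def read_genotypes(path, map_path) -> GenotypeMatrix:
    vals = pd.read_csv(path, sep="\t").to_numpy(dtype=np.int8)
    return GenotypeMatrix(vals, read_marker_map(map_path))


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    codes, _ = pd.factorize(df["strain"], sort=True)
    return PhenotypeTable(
        strain=codes,
        replicate=df["replicate"].to_numpy(),
        value=df["value"].to_numpy(),
        n_strains=int(codes.max()) + 1,
    )


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def import_rdata(genotype_rdata, out_prefix):
    """Convert a deposited RData genotype/phenotype archive to the TSV formats.

    Expects objects named ``gdata`` (segregants x markers, -1/+1) and
    ``pheno_raw`` (per-strain replicate lists). Requires the optional
    ``pyreadr`` dependency.
    """
    try:
        import pyreadr
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "importing RData deposits requires the optional 'pyreadr' package"
        ) from exc
    result = pyreadr.read_r(str(genotype_rdata))  # pragma: no cover
    for name, df in result.items():  # pragma: no cover
        df.to_csv(f"{out_prefix}.{name}.tsv.gz", sep="\t", index=False)
    return list(result)  # pragma: no cover
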