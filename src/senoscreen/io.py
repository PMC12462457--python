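"""Readers and writers for the formats the pipeline exchanges.

Fields are stored as 16-bit single-channel TIFFs named
``<plate>_<well>_f<field>_ch<1|2>.tif``; plate maps, counts and truth
tables as CSV; expression matrices as genes x samples TSV with a sidecar
sample-sheet CSV; signatures as GMT or two-column TSV; DE tables as TSV.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging import ImageField
from .signature import DETable, SignatureSet

_FIELD_RE = re.compile(r"^(?P<plate>.+)_(?P<well>[A-P]\d{2})_f(?P<field>\d+)_ch(?P<ch>[12])\.tif$")


def field_filenames(plate: str, well: str, field: int) -> tuple[str, str]:
    base = f"{plate}_{well}_f{field}"
    return f"{base}_ch1.tif", f"{base}_ch2.tif"


def write_field(field: ImageField, directory: str | Path) -> tuple[Path, Path]:
    """Write both channels of one field as 16-bit grayscale TIFFs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ch1, ch2 = field_filenames(field.plate, field.well, field.field)
    paths = (directory / ch1, directory / ch2)
    tifffile.imwrite(paths[0], field.nuclei_channel.astype(np.uint16))
    tifffile.imwrite(paths[1], field.cytoplasm_channel.astype(np.uint16))
    return paths


def read_field(directory: str | Path, plate: str, well: str, field: int) -> ImageField:
    directory = Path(directory)
    ch1, ch2 = field_filenames(plate, well, field)
    return ImageField(
        nuclei_channel=tifffile.imread(directory / ch1),
        cytoplasm_channel=tifffile.imread(directory / ch2),
        plate=plate, well=well, field=field,
    )


def iter_field_keys(directory: str | Path):
    """Yield (plate, well, field) for every complete channel pair present."""
    directory = Path(directory)
    seen = {}
    for path in sorted(directory.glob("*.tif")):
        m = _FIELD_RE.match(path.name)
        if not m:
            continue
        key = (m["plate"], m["well"], int(m["field"]))
        seen.setdefault(key, set()).add(m["ch"])
    for key, chans in seen.items():
        if chans == {"1", "2"}:
            yield key


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_platemap(platemap: pd.DataFrame, path: str | Path) -> None:
    platemap.to_csv(path, index=False)


def read_platemap(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_expression(counts: pd.DataFrame, samples: pd.DataFrame,
                     matrix_path: str | Path, samples_path: str | Path) -> None:
    counts.to_csv(matrix_path, sep="\t")
    samples.to_csv(samples_path, index=False)


def read_expression(matrix_path: str | Path,
                    samples_path: str | Path | None = None):
    counts = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if samples_path is None:
        return counts
    return counts, pd.read_csv(samples_path)


def write_de_table(det: DETable, path: str | Path) -> None:
    det.table.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path, cell_line: str = "", drug: str = "") -> DETable:
    return DETable(pd.read_csv(path, sep="\t"), cell_line=cell_line, drug=drug)


def write_gmt(signature: SignatureSet, path: str | Path) -> None:
    """Two GMT lines: <name>_UP and <name>_DOWN."""
    with open(path, "w") as fh:
        fh.write("\t".join([f"{signature.name}_UP", f"alpha={signature.alpha}",
                            *signature.up]) + "\n")
        fh.write("\t".join([f"{signature.name}_DOWN", f"alpha={signature.alpha}",
                            *signature.down]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT file -> {set name: gene list} (description field dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_signature_tsv(signature: SignatureSet, path: str | Path) -> None:
    rows = [(g, "up") for g in signature.up] + [(g, "down") for g in signature.down]
    pd.DataFrame(rows, columns=["gene", "direction"]).to_csv(path, sep="\t", index=False)
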