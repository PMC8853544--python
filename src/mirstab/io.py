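"""Readers and writers for the pipeline's tabular interchange formats.

Canonical interchange is tab-delimited UTF-8 text: a count table with probe
rows and sample columns (first column ``probe_id``), a probe annotation
table (``probe_id``, ``probe_class``[, ``merged``]) and a sample annotation
table (``sample_id``, ``group``[, ``subgroup``, ``codeset``]). NanoString
per-sample RCC documents are supported read-only.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, ProbeClass, ValidationError

# RCC CodeClass labels -> probe classes. "Endogenous1/2" variants occur in
# miRNA codesets; SpikeIn/Ligation and Message classes are not modelled.
_RCC_CLASS_MAP = {
    "Endogenous": ProbeClass.ENDOGENOUS.value,
    "Endogenous1": ProbeClass.ENDOGENOUS.value,
    "Endogenous2": ProbeClass.ENDOGENOUS.value,
    "Housekeeping": ProbeClass.HOUSEKEEPING.value,
    "Positive": ProbeClass.POSITIVE.value,
    "Negative": ProbeClass.NEGATIVE.value,
}


def read_count_table(
    path: str | Path,
    probe_annot_path: str | Path,
    sample_annot_path: str | Path,
) -> CountMatrix:
    """Read a TSV count table plus probe and sample annotation TSVs.

    Raises
    ------
    FileNotFoundError
        If any input file is missing.
    ValidationError
        On negative or non-integer counts, or on any mismatch between the
        matrix ids and the annotation tables.
    """
    for p in (path, probe_annot_path, sample_annot_path):
        if not Path(p).is_file():
            raise FileNotFoundError(str(p))
    counts = pd.read_csv(path, sep="\t", index_col="probe_id")
    for col in counts.columns:
        if not np.issubdtype(counts[col].dtype, np.number):
            raise ValidationError(f"non-numeric count in column {col!r}")
    probes = pd.read_csv(probe_annot_path, sep="\t", index_col="probe_id")
    samples = pd.read_csv(sample_annot_path, sep="\t", index_col="sample_id")
    if "merged" in probes.columns:
        probes["merged"] = probes["merged"].astype(bool)
    return CountMatrix(counts=counts, probes=probes, samples=samples)


def write_count_table(
    matrix: CountMatrix,
    path: str | Path,
    probe_annot_path: str | Path,
    sample_annot_path: str | Path,
) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="probe_id")
    matrix.probes.to_csv(probe_annot_path, sep="\t", index_label="probe_id")
    matrix.samples.to_csv(sample_annot_path, sep="\t", index_label="sample_id")


# -- RCC ------------------------------------------------------------------


def _parse_rcc_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("</") and line.endswith(">"):
            current = None
        elif line.startswith("<") and line.endswith(">"):
            current = line[1:-1]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return sections


def _read_one_rcc(path: Path) -> tuple[str, pd.DataFrame]:
    sections = _parse_rcc_sections(path.read_text())
    if "Code_Summary" not in sections:
        raise ValidationError(f"{path}: no Code_Summary section")
    sample_id = path.stem
    for line in sections.get("Sample_Attributes", []):
        key, _, value = line.partition(",")
        if key == "ID" and value:
            sample_id = value
    rows = []
    lines = sections["Code_Summary"]
    header = lines[0].split(",")
    try:
        i_class = header.index("CodeClass")
        i_name = header.index("Name")
        i_count = header.index("Count")
    except ValueError as exc:
        raise ValidationError(f"{path}: malformed Code_Summary header") from exc
    for line in lines[1:]:
        fields = line.split(",")
        if len(fields) < len(header):
            raise ValidationError(f"{path}: unparseable record {line!r}")
        code_class = fields[i_class]
        if code_class not in _RCC_CLASS_MAP:
            continue  # SpikeIn / Message / ligation controls are ignored
        try:
            count = int(float(fields[i_count]))
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric count in {line!r}") from exc
        rows.append((fields[i_name], _RCC_CLASS_MAP[code_class], count))
    frame = pd.DataFrame(rows, columns=["probe_id", "probe_class", "count"])
    if frame["probe_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate probe names")
    return sample_id, frame.set_index("probe_id")


def read_rcc(
    paths: Sequence[str | Path],
    sample_groups: Mapping[str, str] | None = None,
    default_group: str = "unassigned",
) -> CountMatrix:
    """Merge per-sample NanoString RCC documents into one CountMatrix.

    All files must report the identical probe set; a mismatch raises with
    the symmetric difference named. ``sample_groups`` optionally maps
    sample ids to tissue groups.
    """
    if not paths:
        raise ValueError("no RCC files given")
    per_sample: dict[str, pd.DataFrame] = {}
    for p in paths:
        sample_id, frame = _read_one_rcc(Path(p))
        per_sample[sample_id] = frame
    frames = list(per_sample.values())
    reference = set(frames[0].index)
    for sid, frame in per_sample.items():
        diff = reference ^ set(frame.index)
        if diff:
            raise ValidationError(
                f"inconsistent probe sets across RCC files; difference: {sorted(diff)}"
            )
    counts = pd.DataFrame(
        {sid: frame["count"] for sid, frame in per_sample.items()}
    ).loc[list(frames[0].index)]
    probes = frames[0][["probe_class"]].copy()
    probes["merged"] = ["+" in pid for pid in probes.index]
    groups = {
        sid: (sample_groups or {}).get(sid, default_group) for sid in counts.columns
    }
    samples = pd.DataFrame({"group": pd.Series(groups)})
    samples.index.name = "sample_id"
    return CountMatrix(counts=counts, probes=probes, samples=samples)


# -- result tables --------------------------------------------------------


def write_stability_table(table, path: str | Path) -> None:
    """Write a StabilityTable's frame as TSV (probe_id first column)."""
    table.frame.to_csv(path, sep="\t", index_label="probe_id")


def read_stability_frame(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_comparison(results: Iterable, path: str | Path) -> None:
    """Write strategy-comparison results as JSON.

    Each entry carries the pair, the observed rank-distance statistic, the
    unadjusted and BH-adjusted p-values (mirroring the adjusted-(unadjusted)
    presentation of the comparison table), the enumeration mode and the
    number of permutations considered.
    """
    payload = [
        {
            "pair": list(r.pair),
            "union_list": list(r.union_list),
            "T_obs": int(r.T_obs),
            "p_unadjusted": float(r.p_unadjusted),
            "p_adjusted": None if r.p_adjusted is None else float(r.p_adjusted),
            "n_permutations": int(r.n_permutations),
            "mode": r.mode,
        }
        for r in results
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_comparison(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())
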