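"""Per-patient feature matrix across modalities and time points.

Column names follow the pattern ``{Pre|Mid|Post}-{CT|SUV}-{FeatureName}``
for raw timepoint features and ``{Diff1|Diff2|Diff3}-{CT|SUV}-{FeatureName}``
for the three between-timepoint differences:

    Diff1 = Mid - Pre,  Diff2 = Post - Mid,  Diff3 = Post - Pre.

A missing timepoint (e.g. a patient without a mid-treatment scan) leaves
its cells — and every difference involving it — missing; downstream
statistics use pairwise deletion per feature.

The module also ships a packaged fixture: the per-patient serial roundness
table of a 17-patient anal-cancer cohort (4 recurrent, 13 non-recurrent;
one patient lacking the mid-treatment scan), printed to 2 decimals, which
the recurrence models can be exercised against without any image data.
"""

from __future__ import annotations

import importlib.resources
import re

import numpy as np
import pandas as pd

from .grids import ScanSession
from .intensity import compute_intensity_features
from .shape import compute_shape_features
from .texture import compute_texture_features

WINDOWS = ("Pre", "Mid", "Post")
DIFF_WINDOWS = ("Diff1", "Diff2", "Diff3")
MODALITIES = ("CT", "SUV")

_TIMEPOINT_TO_WINDOW = {"pre": "Pre", "mid": "Mid", "post": "Post"}
_NAME_RE = re.compile(
    r"^(Pre|Mid|Post|Diff1|Diff2|Diff3)-(CT|SUV)-([A-Za-z0-9]+)$")


def make_name(window: str, modality: str, feature: str) -> str:
    return f"{window}-{modality}-{feature}"


def parse_name(name: str) -> tuple[str, str, str]:
    """Split a column name into (window, modality, feature)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a recognized feature column name: {name!r}")
    return m.group(1), m.group(2), m.group(3)


def display_name(name: str) -> str:
    """Report dialect, e.g. ``Diff3-CT-Roundness`` -> ``Diff3 CT Roundness``."""
    window, modality, feature = parse_name(name)
    pretty = re.sub(r"(?<!^)(?=[A-Z][a-z])", " ", feature)
    pretty = pretty.replace("Sd Of", "SD of").replace("Mean Of", "Mean of")
    window = {"Pre": "Pre-CRT", "Mid": "Mid-CRT", "Post": "Post-CRT"}.get(
        window, window)
    return f"{window} {modality} {pretty}"


def extract_session_features(session: ScanSession, shape: bool = True,
                             intensity: bool = True,
                             texture: bool = True) -> dict[str, float]:
    """Features of one session, named ``{Window}-{Modality}-{Feature}``.

    Geometry features are computed per modality on the modality's native
    grid (the PET-grid GTV is coarser than the CT-grid GTV, so e.g. its
    surface-voxel count differs); intensity and texture use the matching
    volume.
    """
    window = _TIMEPOINT_TO_WINDOW[session.timepoint]
    out: dict[str, float] = {}
    for modality, vol, mask in (("CT", session.ct, session.gtv_ct),
                                ("SUV", session.suv, session.gtv_suv)):
        if mask.n_foreground == 0:
            raise ValueError(
                f"{session.patient_id}/{session.timepoint}: empty {modality} GTV")
        if not mask.same_grid(vol):
            raise ValueError(
                f"{session.patient_id}/{session.timepoint}: {modality} mask "
                "misaligned with volume")
        feats: dict[str, float] = {}
        if shape:
            feats.update(compute_shape_features(mask).to_dict())
        if intensity:
            feats.update(compute_intensity_features(vol, mask).to_dict())
        if texture:
            feats.update(compute_texture_features(vol, mask))
        out.update({make_name(window, modality, k): v for k, v in feats.items()})
    return out


def extract_all(sessions: list[ScanSession], shape: bool = True,
                intensity: bool = True, texture: bool = True) -> dict[str, float]:
    """One feature row from all available sessions of a single patient."""
    if not sessions:
        raise ValueError("extract_all needs at least one session")
    pids = {s.patient_id for s in sessions}
    if len(pids) != 1:
        raise ValueError(f"sessions from multiple patients: {sorted(pids)}")
    row: dict[str, float] = {}
    for s in sessions:
        row.update(extract_session_features(s, shape, intensity, texture))
    return row


def build_feature_table(sessions: list[ScanSession], shape: bool = True,
                        intensity: bool = True,
                        texture: bool = True) -> pd.DataFrame:
    """Patients x features table (absent timepoints leave missing cells)."""
    by_patient: dict[str, list[ScanSession]] = {}
    for s in sessions:
        by_patient.setdefault(s.patient_id, []).append(s)
    rows = {pid: extract_all(ss, shape, intensity, texture)
            for pid, ss in by_patient.items()}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient_id"
    return table


def compute_diffs(table: pd.DataFrame) -> pd.DataFrame:
    """Append Diff1/2/3 columns for every (modality, feature) present.

    A missing operand propagates to the difference.
    """
    out = table.copy()
    triples: dict[tuple[str, str], dict[str, str]] = {}
    for col in table.columns:
        try:
            window, modality, feature = parse_name(col)
        except ValueError:
            continue
        if window in WINDOWS:
            triples.setdefault((modality, feature), {})[window] = col
    pairs = {"Diff1": ("Mid", "Pre"), "Diff2": ("Post", "Mid"),
             "Diff3": ("Post", "Pre")}
    new_cols = {}
    for (modality, feature), cols in triples.items():
        for dname, (b, a) in pairs.items():
            if b in cols and a in cols:
                new_cols[make_name(dname, modality, feature)] = (
                    table[cols[b]] - table[cols[a]])
    return pd.concat([out, pd.DataFrame(new_cols, index=table.index)], axis=1)


def to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Tidy form: one row per (patient, window, modality, feature)."""
    records = []
    for pid, row in table.iterrows():
        for col, value in row.items():
            window, modality, feature = parse_name(str(col))
            records.append({"patient_id": pid, "window": window,
                            "modality": modality, "feature": feature,
                            "value": value})
    return pd.DataFrame(records)


def load_fixture_roundness() -> tuple[pd.DataFrame, pd.Series]:
    """The packaged 17-patient serial CT roundness table with labels.

    Returns a table with the six columns ``Pre-CT-Roundness`` ...
    ``Diff3-CT-Roundness`` (values as printed, 2 decimals; one patient has
    no mid-treatment scan) and the 0/1 recurrence labels.
    """
    ref = importlib.resources.files("deltarad.data") / "serial_roundness_cohort.csv"
    with importlib.resources.as_file(ref) as path:
        raw = pd.read_csv(path)
    raw = raw.set_index("patient_id")
    labels = raw["recurrence"].astype(int)
    labels.name = "recurrence"
    table = pd.DataFrame({
        make_name("Pre", "CT", "Roundness"): raw["pre"],
        make_name("Mid", "CT", "Roundness"): raw["mid"],
        make_name("Post", "CT", "Roundness"): raw["post"],
        make_name("Diff1", "CT", "Roundness"): raw["diff1"],
        make_name("Diff2", "CT", "Roundness"): raw["diff2"],
        make_name("Diff3", "CT", "Roundness"): raw["diff3"],
    })
    table.index.name = "patient_id"
    return table, labels


def feature_names_in(table: pd.DataFrame) -> list[str]:
    """Columns of ``table`` that parse as feature names (closed registry)."""
    out = []
    for col in table.columns:
        try:
            parse_name(str(col))
        except ValueError:
            continue
        out.append(str(col))
    return out
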