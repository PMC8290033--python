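"""Plain-text readers/writers for every pipeline artefact.

All interchange formats are inspectable text: CSV/TSV tables with header
rows, one CSV matrix per subject for raw EEG and per subject x band for
PLV matrices, and JSON sidecars for feature-modality tags.  Epoch arrays,
which are intermediate and bulky, use NumPy ``.npz``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import PLVMatrix
from .eeg_preprocess import EEGRecording, EpochSet
from .feature_assembly import FeatureTable

__all__ = [
    "write_cohort", "read_cohort",
    "write_eeg", "read_eeg",
    "write_table", "read_table",
    "write_plv", "read_plv",
    "write_epochs", "read_epochs",
    "write_feature_table", "read_feature_table",
]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index_label="subject_id")
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


def write_eeg(rec: EEGRecording, path: str | Path) -> Path:
    """One CSV per subject: rows = channels, columns = samples.

    The sampling rate is carried in a leading comment line.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n")
        pd.DataFrame(rec.data, index=rec.channel_names).to_csv(fh, header=False)
    return path


def read_eeg(path: str | Path) -> EEGRecording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, header=None, index_col=0)
    return EEGRecording(data=df.to_numpy(), fs=fs, channel_names=[str(c) for c in df.index])


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Subjects-in-rows TSV with a header row (taxa and blood tables)."""
    path = Path(path)
    df.to_csv(path, sep="\t", index_label="subject_id")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")


def write_plv(m: PLVMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(m.values, index=m.channel_names, columns=m.channel_names).to_csv(path)
    return path


def read_plv(path: str | Path, band_label: str = "", n_epochs: int = 0) -> PLVMatrix:
    df = pd.read_csv(path, index_col=0)
    return PLVMatrix(values=df.to_numpy(), band_label=band_label,
                     n_epochs_averaged=n_epochs, channel_names=[str(c) for c in df.index])


def write_epochs(bands: dict[str, EpochSet], path: str | Path) -> Path:
    """All band epoch sets of one subject in one ``.npz`` file."""
    path = Path(path)
    arrays = {f"epochs_{b}": es.epochs for b, es in bands.items()}
    any_es = next(iter(bands.values()))
    meta = {
        "fs": any_es.fs,
        "epoch_length": any_es.epoch_length,
        "channel_names": list(any_es.channel_names),
        "bands": list(bands),
    }
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)
    return path


def read_epochs(path: str | Path) -> dict[str, EpochSet]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        out = {}
        for band in meta["bands"]:
            out[band] = EpochSet(
                epochs=z[f"epochs_{band}"],
                fs=meta["fs"],
                epoch_length=meta["epoch_length"],
                band_label=band,
                channel_names=meta["channel_names"],
            )
    return out


def write_feature_table(ft: FeatureTable, path: str | Path) -> Path:
    """Feature CSV plus a JSON sidecar holding modality tags and group labels."""
    path = Path(path)
    ft.data.to_csv(path, index_label="subject_id")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "modality": ft.modality,
        "groups": ft.groups.to_dict(),
    }, indent=1))
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    data = pd.read_csv(path, index_col="subject_id")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FeatureTable(
        data=data,
        modality=meta["modality"],
        groups=pd.Series(meta["groups"]).reindex(data.index),
    )
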