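"""Reading and writing epoch sets.

Canonical on-disk form is a ``manifest.json`` naming the metadata plus one
plain CSV per trial (row = channel, comma separated, no header, values in
microvolts printed at 10 significant digits). An adapter for epoched
EEGLAB ``.set`` datasets (MAT files) is provided; it converts into the
canonical model and unit convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io

from .data_model import EpochSet

__all__ = ["read_epochs", "write_epochs", "import_eeglab_set"]

_CSV_FMT = "%.10g"
MANIFEST_NAME = "manifest.json"


def write_epochs(epochs: EpochSet, out_dir) -> Path:
    """Write ``epochs`` to ``out_dir`` in the canonical dialect.

    Returns the path of the manifest written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trial_entries = []
    for i, (trial, label) in enumerate(zip(epochs.trials, epochs.labels)):
        fname = f"trial_{i + 1:04d}.csv"
        np.savetxt(out_dir / fname, trial, fmt=_CSV_FMT, delimiter=",")
        trial_entries.append({"file": fname, "label": label})
    manifest = {
        "sampling_rate_hz": epochs.sampling_rate,
        "onset_index": epochs.onset_index,
        "band_tag": epochs.band_tag,
        "channels": list(epochs.channel_names),
        "trials": trial_entries,
    }
    manifest_path = out_dir / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_epochs(manifest_path) -> EpochSet:
    """Read an :class:`EpochSet` from a canonical manifest.

    ``manifest_path`` may be the manifest file itself or a directory
    containing ``manifest.json``.
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent

    trials, labels = [], []
    shape = None
    for i, entry in enumerate(manifest["trials"]):
        csv_path = base / entry["file"]
        if not csv_path.exists():
            raise FileNotFoundError(
                f"trial {i + 1} ({entry['file']}): CSV file missing"
            )
        mat = np.loadtxt(csv_path, delimiter=",", ndmin=2)
        if shape is None:
            shape = mat.shape
        elif mat.shape != shape:
            raise ValueError(
                f"trial {i + 1} ({entry['file']}): shape {mat.shape} does not "
                f"match first trial {shape}"
            )
        trials.append(mat)
        labels.append(entry["label"])

    return EpochSet(
        trials=trials,
        labels=labels,
        channel_names=list(manifest["channels"]),
        sampling_rate=float(manifest["sampling_rate_hz"]),
        onset_index=int(manifest["onset_index"]),
        band_tag=manifest.get("band_tag", "raw"),
    )


def _eeg_struct(path):
    """Return the EEG struct from a .set MAT file (attribute access)."""
    raw = scipy.io.loadmat(path, squeeze_me=True, struct_as_record=False)
    if "EEG" in raw:
        return raw["EEG"]
    # older EEGLAB files store fields as top-level variables
    class _Bag:  # noqa: D401 - tiny adapter
        pass

    bag = _Bag()
    for k, v in raw.items():
        if not k.startswith("__"):
            setattr(bag, k, v)
    return bag


def _epoch_event_codes(eeg, n_epochs: int):
    """One event code per epoch: the first event type of each epoch."""
    codes = []
    epoch_field = getattr(eeg, "epoch", None)
    if epoch_field is not None and np.size(epoch_field) == n_epochs:
        epochs = np.atleast_1d(epoch_field)
        for ep in epochs:
            et = ep.eventtype
            first = np.atleast_1d(et)[0] if np.size(et) > 1 else et
            codes.append(str(first))
        return codes
    # fall back to the flat event table, keyed by its epoch field
    events = np.atleast_1d(eeg.event)
    by_epoch: dict = {}
    for ev in events:
        idx = int(np.atleast_1d(ev.epoch)[0])
        by_epoch.setdefault(idx, str(ev.type))
    return [by_epoch[i + 1] for i in range(n_epochs)]


def import_eeglab_set(path, event_map: dict) -> EpochSet:
    """Import an epoched EEGLAB ``.set`` dataset.

    Parameters
    ----------
    path : path-like
        The ``.set`` file (MAT format with data embedded).
    event_map : dict
        Maps EEGLAB event-type codes (as strings) to the label alphabet.

    Notes
    -----
    EEGLAB stores epoched data as ``channels x samples x trials``. Values
    are taken to be microvolts already (the EEGLAB convention); no
    rescaling is applied.
    """
    eeg = _eeg_struct(path)
    data = np.asarray(eeg.data, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(
            "dataset is continuous (2-D data); epoch it first, e.g. with "
            "segment_epochs()"
        )
    n_ch, n_samp, n_epochs = data.shape
    codes = _epoch_event_codes(eeg, n_epochs)
    unknown = sorted({c for c in codes if c not in event_map})
    if unknown:
        raise KeyError(
            f"event codes not present in mapping: {unknown}; "
            f"known codes: {sorted(event_map)}"
        )
    labels = [event_map[c] for c in codes]

    chanlocs = getattr(eeg, "chanlocs", None)
    if chanlocs is not None and np.size(chanlocs) == n_ch:
        channel_names = [str(c.labels) for c in np.atleast_1d(chanlocs)]
    else:
        channel_names = [f"ch{i + 1}" for i in range(n_ch)]

    rate = float(eeg.srate)
    xmin = float(getattr(eeg, "xmin", 0.0))  # seconds, usually negative
    onset_index = int(round(-xmin * rate))

    return EpochSet(
        trials=[data[:, :, i] for i in range(n_epochs)],
        labels=labels,
        channel_names=channel_names,
        sampling_rate=rate,
        onset_index=max(onset_index, 0),
        band_tag="raw",
    )
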