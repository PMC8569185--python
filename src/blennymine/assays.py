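"""Containers for pharmacological assay measurements and their CSV form.

All assay data travel as long-format CSV with columns
(dataset_id, replicate, concentration_nM or time_s, channel, value), which is
also the layout accepted from real plate-reader exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from blennymine.exceptions import InputError


@dataclass
class BindingDataset:
    """Competition radioligand displacement measurements (total binding, cpm)."""

    ligand_id: str
    replicates: list[tuple[float, float]]  # (concentration nM, cpm)
    radioligand_conc: float  # [L], nM
    radioligand_kd: float  # Kd, nM
    nonspecific_cpm: float  # operational NS level (10 uM naloxone condition)

    def __post_init__(self) -> None:
        if any(c <= 0 for c, _ in self.replicates):
            raise InputError("binding concentrations must be positive")
        if any(y < 0 for _, y in self.replicates):
            raise InputError("cpm values must be non-negative")

    @property
    def n_concentrations(self) -> int:
        return len({c for c, _ in self.replicates})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dataset_id": self.ligand_id,
                "replicate": i,
                "concentration_nM": c,
                "channel": "cpm",
                "value": y,
            }
            for i, (c, y) in enumerate(self.replicates)
        ]
        return pd.DataFrame(rows)


@dataclass
class DoseResponseDataset:
    """cAMP-inhibition concentration-response data (raw or percent scale)."""

    ligand_id: str
    replicates: list[tuple[float, float]]  # (concentration nM, response)
    reference_response_at_10uM: float
    scale: str = "raw"  # "raw" or "percent"

    def __post_init__(self) -> None:
        if any(c <= 0 for c, _ in self.replicates):
            raise InputError("concentrations must be positive")

    @property
    def n_concentrations(self) -> int:
        return len({c for c, _ in self.replicates})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dataset_id": self.ligand_id,
                "replicate": i,
                "concentration_nM": c,
                "channel": f"response_{self.scale}",
                "value": y,
            }
            for i, (c, y) in enumerate(self.replicates)
        ]
        return pd.DataFrame(rows)


@dataclass
class BRETTrace:
    """A BRET kinetic trace: donor (460 nm) and acceptor (510 nm) emissions."""

    ligand_id: str
    times: np.ndarray  # seconds, strictly increasing
    em460: np.ndarray  # luminescence counts (Nluc donor)
    em510: np.ndarray  # fluorescence counts (EGFP acceptor)
    addition_time: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.em460 = np.asarray(self.em460, dtype=float)
        self.em510 = np.asarray(self.em510, dtype=float)
        if not (len(self.times) == len(self.em460) == len(self.em510)):
            raise InputError("BRET trace arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("BRET trace times must be strictly increasing")
        if np.any(self.em460 <= 0) or np.any(self.em510 <= 0):
            raise InputError("BRET emission counts must be positive")
        if int(np.sum(self.times < self.addition_time)) < 2:
            raise InputError("BRET trace needs >=2 baseline samples before addition")

    @property
    def ratio(self) -> np.ndarray:
        """Acceptor/donor emission ratio (em510/em460)."""
        return self.em510 / self.em460

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for channel, values in (("em460", self.em460), ("em510", self.em510)):
            frames.append(
                pd.DataFrame(
                    {
                        "dataset_id": self.ligand_id,
                        "replicate": 0,
                        "time_s": self.times,
                        "channel": channel,
                        "value": values,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def binding_from_frame(
    df: pd.DataFrame,
    radioligand_conc: float,
    radioligand_kd: float,
    nonspecific_cpm: float = 0.0,
) -> BindingDataset:
    """Rebuild a BindingDataset from long-format rows of a single dataset_id."""
    ids = df["dataset_id"].unique()
    if len(ids) != 1:
        raise InputError(f"expected one dataset_id, found {list(ids)}")
    pairs = [
        (float(r["concentration_nM"]), float(r["value"]))
        for _, r in df.iterrows()
        if r["channel"] == "cpm"
    ]
    return BindingDataset(
        ligand_id=str(ids[0]),
        replicates=pairs,
        radioligand_conc=radioligand_conc,
        radioligand_kd=radioligand_kd,
        nonspecific_cpm=nonspecific_cpm,
    )


def dose_response_from_frame(
    df: pd.DataFrame, reference_response_at_10uM: float
) -> DoseResponseDataset:
    ids = df["dataset_id"].unique()
    if len(ids) != 1:
        raise InputError(f"expected one dataset_id, found {list(ids)}")
    channels = df["channel"].unique()
    scale = "percent" if "response_percent" in channels else "raw"
    pairs = [
        (float(r["concentration_nM"]), float(r["value"]))
        for _, r in df.iterrows()
        if str(r["channel"]).startswith("response")
    ]
    return DoseResponseDataset(
        ligand_id=str(ids[0]),
        replicates=pairs,
        reference_response_at_10uM=reference_response_at_10uM,
        scale=scale,
    )


def bret_from_frame(df: pd.DataFrame, addition_time: float = 0.0) -> BRETTrace:
    ids = df["dataset_id"].unique()
    if len(ids) != 1:
        raise InputError(f"expected one dataset_id, found {list(ids)}")
    wide = df.pivot_table(index="time_s", columns="channel", values="value")
    if "em460" not in wide.columns or "em510" not in wide.columns:
        raise InputError("BRET table must contain em460 and em510 channels")
    wide = wide.sort_index()
    return BRETTrace(
        ligand_id=str(ids[0]),
        times=wide.index.to_numpy(),
        em460=wide["em460"].to_numpy(),
        em510=wide["em510"].to_numpy(),
        addition_time=addition_time,
    )
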