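"""Bypass-efficiency and mutation-frequency estimators.

The assay's readout is band densitometry.  For each lesion construct k the
relative incorporation efficiency is the loading-normalized 20-mer ratio

    e_k = (I20_k / I24_k) / (I20_STD / I24_STD),

where I20 is the diagnostic 20-mer intensity under PstI+HindIII digestion
and I24 the 24-mer construction-check intensity under EcoRI+HindIII (the
loading control).  A construct whose 20-mer band is absent contributes
e_k = 0, matching a binary band-present/absent gel reading.  The relative
bypass efficiency (RBE) is the sum of the four incorporation efficiencies,
and the mutation frequency of outcome k is its normalized share,
f_k = e_k / sum_j e_j (undefined, and explicitly flagged so, when RBE = 0).

Normalization by the 24-mer band is on by default; because the wording of
the source protocol is ambiguous on this point a flag selects the
unnormalized variant, and the two coincide exactly under equal loading.
Both estimators are invariant to any global intensity rescaling.

A percentile bootstrap over replicate gels provides interval estimates; the
underlying assay reports single-gel point values only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constructs import DecodeTable, STD_NAME
from .gel import DIAGNOSTIC_LENGTH, PROTOCOL_EH, PROTOCOL_PH, PROTOCOLS
from .seq_core import ControlError, DataError


def _band_intensity(
    bands: pd.DataFrame, sample: str, protocol: str, length: int
) -> float | None:
    sel = bands.loc[
        (bands["sample"] == sample)
        & (bands["protocol"] == protocol)
        & (bands["length_nt"] == length),
        "intensity",
    ]
    if len(sel) == 0:
        return None
    if len(sel) > 1:
        raise DataError(
            f"duplicate band rows for ({sample}, {protocol}, {length} nt)"
        )
    return float(sel.iloc[0])


def incorporation_efficiency(
    bands: pd.DataFrame,
    construct: str,
    std: str = STD_NAME,
    normalize: bool = True,
) -> float:
    """Relative incorporation efficiency e_k for one construct.

    Raises :class:`DataError` if the construct's 24-mer construction-check
    band is missing (failed construction) and :class:`ControlError` if the
    control's bands are missing or zero.
    """
    n20, n24 = DIAGNOSTIC_LENGTH[PROTOCOL_PH], DIAGNOSTIC_LENGTH[PROTOCOL_EH]
    i20_std = _band_intensity(bands, std, PROTOCOL_PH, n20)
    if i20_std is None or i20_std <= 0:
        raise ControlError(
            f"control {std!r} has no positive {n20}-mer band; cannot normalize"
        )
    i24_k = _band_intensity(bands, construct, PROTOCOL_EH, n24)
    if i24_k is None or i24_k <= 0:
        raise DataError(
            f"{construct!r}: {n24}-mer construction-check band missing "
            "(failed construction)"
        )
    i20_k = _band_intensity(bands, construct, PROTOCOL_PH, n20)
    if i20_k is None:  # absent band reads as zero incorporation
        return 0.0
    if not normalize:
        return i20_k / i20_std
    i24_std = _band_intensity(bands, std, PROTOCOL_EH, n24)
    if i24_std is None or i24_std <= 0:
        raise ControlError(
            f"control {std!r} has no positive {n24}-mer loading band"
        )
    return (i20_k / i24_k) / (i20_std / i24_std)


@dataclass(frozen=True)
class BypassResult:
    """Per-construct incorporation efficiencies and derived summaries.

    ``rbe`` and the ``f`` entries are stored as fractions at full precision;
    the ``*_pct`` properties report percentages.  ``f`` is ``None`` when
    RBE = 0 (mutation frequencies undefined), never NaN.
    """

    lesion: str
    e: Mapping[str, float]
    rbe: float
    f: Mapping[str, float] | None
    labels: Mapping[str, str]

    @property
    def mf_defined(self) -> bool:
        return self.f is not None

    @property
    def rbe_pct(self) -> float:
        return 100.0 * self.rbe

    @property
    def f_pct(self) -> dict[str, float] | None:
        if self.f is None:
            return None
        return {k: 100.0 * v for k, v in self.f.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, ek in self.e.items():
            rows.append(
                {
                    "lesion": self.lesion,
                    "construct": name,
                    "e_k": ek,
                    "RBE_pct": self.rbe_pct,
                    "f_k_pct": 100.0 * self.f[name] if self.f is not None else "",
                    "outcome_label": self.labels[name],
                }
            )
        return pd.DataFrame(rows)

    def report(self) -> str:
        """Human-readable summary; percentages rounded for display only."""
        lines = [
            f"lesion l-d{self.lesion}: relative bypass efficiency "
            f"{self.rbe_pct:.0f}%"
        ]
        if self.f is None:
            lines.append("  mutation frequencies undefined (no bypass detected)")
        else:
            for name, ek in self.e.items():
                if ek > 0:
                    lines.append(
                        f"  {name} [{self.labels[name]}]: e={ek:.4f}, "
                        f"frequency {100 * self.f[name]:.0f}%"
                    )
        return "\n".join(lines)


def quantify(
    bands: pd.DataFrame, decode: DecodeTable, normalize: bool = True
) -> BypassResult:
    """Estimate RBE and mutation frequencies from one band table.

    The table must contain all four lesion constructs and the STD control
    under both digestion protocols.
    """
    samples = set(decode.construct_names) | {STD_NAME}
    present = {
        (s, p)
        for s, p in zip(bands["sample"], bands["protocol"])
    }
    missing = [
        (s, p) for s in sorted(samples) for p in PROTOCOLS if (s, p) not in present
    ]
    if any(s == STD_NAME for s, _ in missing):
        raise ControlError(f"control {STD_NAME!r} missing from band table: {missing}")
    if missing:
        raise DataError(f"samples missing from band table: {missing}")
    e = {
        name: incorporation_efficiency(bands, name, normalize=normalize)
        for name in decode.construct_names
    }
    rbe = float(sum(e.values()))
    f = {k: v / rbe for k, v in e.items()} if rbe > 0 else None
    labels = {name: decode.label(name) for name in decode.construct_names}
    return BypassResult(lesion=decode.lesion, e=e, rbe=rbe, f=f, labels=labels)


def mean_result(results: Sequence[BypassResult]) -> BypassResult:
    """Replicate-averaged result: mean e_k, with RBE and f recomputed."""
    if not results:
        raise DataError("no results to average")
    names = list(results[0].e)
    e = {n: float(np.mean([r.e[n] for r in results])) for n in names}
    rbe = float(sum(e.values()))
    f = {k: v / rbe for k, v in e.items()} if rbe > 0 else None
    return BypassResult(
        lesion=results[0].lesion, e=e, rbe=rbe, f=f, labels=results[0].labels
    )


@dataclass(frozen=True)
class BootstrapIntervals:
    """Percentile-bootstrap intervals for RBE and each mutation frequency."""

    level: float
    rbe: tuple[float, float]
    f: Mapping[str, tuple[float, float]] | None


def bootstrap_ci(
    tables: Sequence[pd.DataFrame],
    decode: DecodeTable,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    normalize: bool = True,
) -> BootstrapIntervals:
    """Percentile bootstrap over replicate band tables.

    Resamples replicates with replacement ``n_boot`` times and takes
    percentiles of the resampled replicate-mean estimates.  Requires at
    least two replicates; reproducible under a fixed seed.
    """
    if len(tables) < 2:
        raise DataError(
            f"bootstrap needs >= 2 replicate band tables, got {len(tables)}"
        )
    results = [quantify(t, decode, normalize=normalize) for t in tables]
    names = list(results[0].e)
    e_mat = np.array([[r.e[n] for n in names] for r in results])  # (reps, 4)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(tables), size=(n_boot, len(tables)))
    boot_e = e_mat[idx].mean(axis=1)  # (n_boot, 4)
    boot_rbe = boot_e.sum(axis=1)
    alpha = 100 * (1 - level) / 2
    rbe_ci = tuple(np.percentile(boot_rbe, [alpha, 100 - alpha]))
    f_ci = None
    if np.all(boot_rbe > 0):
        boot_f = boot_e / boot_rbe[:, None]
        f_ci = {
            n: tuple(np.percentile(boot_f[:, j], [alpha, 100 - alpha]))
            for j, n in enumerate(names)
        }
    return BootstrapIntervals(level=level, rbe=rbe_ci, f=f_ci)


def write_result(result: BypassResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)
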