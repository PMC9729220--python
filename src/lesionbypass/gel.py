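"""Synthetic gel densitometry: synthetic-data stage 2.

Turns simulated progeny pools into noisy band-intensity tables emulating
SYBR-stained 20% denaturing PAGE quantification.  Every progeny species is
digested in silico under the requested protocol, fragments are binned by
single-strand length, and the mean intensity of a band is proportional to
(molar amount x fragment length) — SYBR staining is approximately
mass-proportional.  Measurement noise is i.i.d. multiplicative log-normal
per band (the real assay reports single gel measurements without an error
model, so a simple, explicit one is used; sigma is the standard deviation
of log intensity, default 0.05).

Two digestion protocols are modeled:

* ``EcoRI+HindIII`` — the construction check.  It is applied to the input
  recombinant pool, so the released 24-mer band is proportional to loaded
  material and independent of bypass; it serves as the loading control the
  quantification normalizes by.
* ``PstI+HindIII`` — the product readout.  It is applied to the replicated
  progeny pool; only site-restored progeny release the diagnostic 20-mer.

A configurable background band (default length 16) can be added to the
PstI+HindIII lanes, standing for self-ligated vector, at a stated fraction
of the control 20-mer signal; it never overlaps the 20/24-mer bands and so
never interferes with quantification.  Bands below a detection floor
(default 1% of the control's diagnostic band) are reported as absent,
mirroring a binary band-present/absent gel readout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constructs import (
    Construct,
    DecodeTable,
    build_constructs,
    com20_amplicon,
    decode_table,
    export_constructs,
    progeny_amplicon,
    recombinant_amplicon,
    write_decode_table,
    STD_NAME,
)
from .restriction import ECORI, HINDIII, PSTI, digest
from .seq_core import ConfigError, ControlError, DataError
from .simulate import (
    BASES,
    LesionParams,
    ProgenyPool,
    expected_pool,
    replicate,
    write_manifest,
)

PROTOCOL_EH = "EcoRI+HindIII"
PROTOCOL_PH = "PstI+HindIII"
PROTOCOLS = (PROTOCOL_EH, PROTOCOL_PH)

_PROTOCOL_ENZYMES = {
    PROTOCOL_EH: (ECORI, HINDIII),
    PROTOCOL_PH: (PSTI, HINDIII),
}

#: Diagnostic band length per protocol (used as the detection-floor reference).
DIAGNOSTIC_LENGTH = {PROTOCOL_EH: 24, PROTOCOL_PH: 20}

BAND_COLUMNS = ("sample", "protocol", "length_nt", "intensity")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal densitometry noise; sigma in log units."""

    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigError(f"sigma: must be >= 0, got {self.sigma}")


def synthesize_gel(
    pools: Sequence[ProgenyPool],
    protocol: str,
    noise: NoiseModel = NoiseModel(sigma=0.0),
    background_16mer: float = 0.0,
    background_length: int = 16,
    detection_floor: float = 0.01,
) -> pd.DataFrame:
    """Digest every pool under ``protocol`` and return a noisy band table.

    The pools must include the STD control.  Returns a DataFrame with
    columns (sample, protocol, length_nt, intensity); (sample, protocol,
    length_nt) is unique per row.
    """
    if protocol not in PROTOCOLS:
        raise ConfigError(f"protocol: must be one of {PROTOCOLS}, got {protocol!r}")
    names = [p.name for p in pools]
    if STD_NAME not in names:
        raise ControlError(f"pools must include the {STD_NAME} control; got {names}")
    enzymes = _PROTOCOL_ENZYMES[protocol]

    rows: list[list] = []  # sample, length, mean intensity
    for pool in pools:
        acc: dict[int, float] = {}
        if protocol == PROTOCOL_EH:
            species = [(recombinant_amplicon(pool.construct), float(pool.n_templates))]
        else:
            species = [
                (progeny_amplicon(pool.construct, key), float(count))
                for key, count in pool.counts.items()
                if count
            ]
            species.append((com20_amplicon(), float(pool.com20)))
        for duplex, moles in species:
            if moles <= 0:
                continue
            for frag in digest(duplex, enzymes):
                acc[frag.length] = acc.get(frag.length, 0.0) + moles * frag.length
        for length in sorted(acc):
            rows.append([pool.name, length, acc[length]])

    df = pd.DataFrame(rows, columns=["sample", "length_nt", "mean"])

    # stable row order before drawing noise, for seed reproducibility
    order = {n: i for i, n in enumerate(names)}
    df = df.sort_values(
        by=["sample", "length_nt"],
        key=lambda s: s.map(order) if s.name == "sample" else s,
        ignore_index=True,
    )
    rng = np.random.default_rng(noise.seed)
    factors = np.exp(noise.sigma * rng.standard_normal(len(df)))
    df["intensity"] = df["mean"].to_numpy() * factors

    # self-ligation background, appended after the main noise draws so its
    # presence never perturbs any other band's value
    if protocol == PROTOCOL_PH and background_16mer > 0:
        std20 = df.loc[
            (df["sample"] == STD_NAME) & (df["length_nt"] == DIAGNOSTIC_LENGTH[protocol]),
            "mean",
        ]
        level = background_16mer * float(std20.iloc[0]) if len(std20) else 0.0
        bg_factors = np.exp(noise.sigma * rng.standard_normal(len(names)))
        extra = pd.DataFrame(
            {
                "sample": list(names),
                "length_nt": background_length,
                "mean": level,
                "intensity": level * bg_factors,
            }
        )
        df = pd.concat([df, extra], ignore_index=True)

    # detection floor relative to the control's diagnostic band
    ref_len = DIAGNOSTIC_LENGTH[protocol]
    ref = df.loc[
        (df["sample"] == STD_NAME) & (df["length_nt"] == ref_len), "intensity"
    ]
    if len(ref):
        floor = detection_floor * float(ref.iloc[0])
        df = df[df["intensity"] >= floor]
    df = df.assign(protocol=protocol)[list(BAND_COLUMNS)].reset_index(drop=True)
    return df


def write_band_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_band_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if tuple(df.columns) != BAND_COLUMNS:
        raise DataError(f"band table {path} must have columns {BAND_COLUMNS}")
    return df


# ---------------------------------------------------------------------------
# Scenario configuration and the synthetic-data entry point
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """One polymerase/lesion scenario for the synthetic-data generator."""

    lesion: str
    beta: float
    pi: Mapping[str, float]
    polymerase: str = ""
    n_templates: int = 100_000
    sigma: float = 0.05
    replicates: int = 1
    seeds: tuple[int, ...] = (1,)
    pool_seed: int | None = None  # default: derived from seeds[0]
    indel_prob: float = 0.0
    background_16mer: float = 0.0
    detection_floor: float = 0.01
    #: use the deterministic expected species composition instead of a
    #: sampled pool (the noise-free limit of the generator)
    expected: bool = False

    def __post_init__(self) -> None:
        if self.lesion not in "ACGT" or len(self.lesion) != 1:
            raise ConfigError(f"lesion: must be one of A/C/G/T, got {self.lesion!r}")
        if self.replicates < 1:
            raise ConfigError(f"replicates: must be >= 1, got {self.replicates}")
        if len(self.seeds) != self.replicates:
            raise ConfigError(
                f"seeds: need exactly {self.replicates} (one per replicate), "
                f"got {len(self.seeds)}"
            )
        if self.n_templates < 1:
            raise ConfigError(f"n_templates: must be >= 1, got {self.n_templates}")
        if self.sigma < 0:
            raise ConfigError(f"sigma: must be >= 0, got {self.sigma}")
        try:
            self.params()
        except Exception as exc:  # surface with the offending field named
            raise ConfigError(f"beta/pi/indel_prob: {exc}") from None

    def params(self) -> LesionParams:
        return LesionParams(beta=self.beta, pi=dict(self.pi), indel_prob=self.indel_prob)

    def resolved_pool_seed(self) -> int:
        if self.pool_seed is not None:
            return self.pool_seed
        return (self.seeds[0] * 7919 + 13) % 2**31


_FLOAT_KEYS = {"beta", "sigma", "indel_prob", "background_16mer", "detection_floor"}
_INT_KEYS = {"n_templates", "replicates", "pool_seed"}


def parse_scenario_config(path: str | Path) -> ScenarioConfig:
    """Parse a flat ``key = value`` scenario file.

    Recognized keys: lesion, polymerase, beta, pi_A, pi_C, pi_G, pi_T,
    n_templates, sigma, replicates, seeds (comma-separated), pool_seed,
    indel_prob, background_16mer, detection_floor.  ``#`` starts a comment.
    """
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        kv[key] = value
    kwargs: dict = {}
    pi: dict[str, float] = {}
    for key, value in kv.items():
        try:
            if key.startswith("pi_") and key[3:] in BASES:
                pi[key[3:]] = float(value)
            elif key == "expected":
                kwargs[key] = value.strip().lower() in ("1", "true", "yes")
            elif key in _FLOAT_KEYS:
                kwargs[key] = float(value)
            elif key in _INT_KEYS:
                kwargs[key] = int(value)
            elif key == "seeds":
                kwargs[key] = tuple(int(s) for s in value.split(",") if s.strip())
            elif key in ("lesion", "polymerase"):
                kwargs[key] = value
            else:
                raise ConfigError(f"{key}: unknown configuration key")
        except ValueError:
            raise ConfigError(f"{key}: could not parse value {value!r}") from None
    if "lesion" not in kwargs:
        raise ConfigError("lesion: missing (required)")
    if "beta" not in kwargs:
        raise ConfigError("beta: missing (required)")
    if not pi:
        raise ConfigError("pi_A/pi_C/pi_G/pi_T: missing (at least one required)")
    kwargs.setdefault("replicates", len(kwargs.get("seeds", (1,))))
    return ScenarioConfig(pi=pi, **kwargs)


def simulate_pools(config: ScenarioConfig) -> tuple[list[ProgenyPool], DecodeTable]:
    """Replicate all five constructs of the scenario once (shared by replicates)."""
    constructs = build_constructs(config.lesion)
    params = config.params()
    base = config.resolved_pool_seed()
    if config.expected:
        pools = [expected_pool(c, params, config.n_templates) for c in constructs]
    else:
        pools = [
            replicate(c, params, config.n_templates, seed=(base + i) % 2**31)
            for i, c in enumerate(constructs)
        ]
    return pools, decode_table(config.lesion)


def replicate_band_table(
    pools: Sequence[ProgenyPool], config: ScenarioConfig, rep: int
) -> pd.DataFrame:
    """Both-protocol band table for replicate ``rep`` (0-based).

    Replicates share the progeny pool and differ only by densitometry noise;
    the two protocols draw independent noise streams derived from the
    replicate seed.
    """
    seed = config.seeds[rep]
    tables = []
    for k, protocol in enumerate(PROTOCOLS):
        tables.append(
            synthesize_gel(
                pools,
                protocol,
                noise=NoiseModel(sigma=config.sigma, seed=(2 * seed + k) % 2**31),
                background_16mer=config.background_16mer,
                detection_floor=config.detection_floor,
            )
        )
    return pd.concat(tables, ignore_index=True)


def generate_experiment(config: ScenarioConfig, outdir: str | Path) -> dict:
    """Emit a complete, self-contained synthetic dataset for one scenario.

    Writes construct FASTA + annotation + decode table, one band-table TSV
    per replicate, and the ground-truth manifest.  Returns the file paths
    plus the in-memory tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    constructs = build_constructs(config.lesion)
    pools, dt = simulate_pools(config)
    params = config.params()
    base = config.resolved_pool_seed()

    fasta = outdir / "constructs.fasta"
    annot = outdir / "constructs_annotations.tsv"
    decode_path = outdir / "decode.tsv"
    manifest = outdir / "truth.tsv"
    export_constructs(constructs, fasta, annot)
    write_decode_table(dt, decode_path)
    write_manifest(
        manifest,
        [
            (c, params, (base + i) % 2**31, config.n_templates)
            for i, c in enumerate(constructs)
        ],
    )
    band_paths = []
    tables = []
    for rep in range(config.replicates):
        df = replicate_band_table(pools, config, rep)
        path = outdir / f"bands_rep{rep + 1}.tsv"
        write_band_table(df, path)
        band_paths.append(path)
        tables.append(df)
    return {
        "fasta": fasta,
        "annotations": annot,
        "decode": decode_path,
        "manifest": manifest,
        "bands": band_paths,
        "tables": tables,
        "pools": pools,
        "decode_table": dt,
    }
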