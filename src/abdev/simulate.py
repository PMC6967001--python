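"""Synthetic Fv panels with known statistical structure.

Sequences are built from fixed synthetic framework scaffolds that carry
exactly the anchor motifs the CDR rules require (FR1/FR3 cysteines, the
FR2 tryptophan, W-G-x-G / F-G-x-G framework-4 starts); CDR contents and
lengths are drawn uniformly within each rule's permitted window, so
:func:`abdev.cdr.find_cdrs` succeeds on every generated record. The
scaffolds are deliberately artificial — they are not germline sequences
and exist solely to satisfy the anchor rules.

Responses emulate the 137-antibody, 12-assay reference panel: each
platform is a linear combination of true features plus Gaussian or Gumbel
noise (several assay distributions are extreme-value shaped), scaled to a
plausible assay range, with the configured fraction of HIC values
replaced by the 25-min censoring sentinel. True coefficients and realized
signal fractions are recorded in the dataset provenance so recovery tests
can check against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cdr import find_cdrs
from .errors import DegenerateDataError
from .features import feature_table
from .io import Dataset, FvRecord

_EULER_GAMMA = float(np.euler_gamma)

# Framework interiors are deterministic slices of this filler; it avoids
# C/W (anchor residues), F (FR4 motif start) and K/R (the H2 terminator)
# so no spurious anchor can arise inside a framework block.
_FILLER = "ASTGLNQDEHIPMVY"


def _fill(n: int, phase: int = 0) -> str:
    s = _FILLER * (n // len(_FILLER) + 2)
    return s[phase: phase + n]


# Synthetic scaffolds. Lengths encode the fixed inter-CDR gaps of the
# anchor rules (FR2-light = 15, FR3-light = 32 ending in Cys, etc.).
VL_FR1 = _fill(22, 0) + "C"                   # 23; anchor Cys at index 22
VL_FR2 = "W" + _fill(14, 3)                   # 15; Trp closes L1
VL_FR3 = _fill(31, 5) + "C"                   # 32; anchor Cys precedes L3
VL_FR4 = "FGSG" + _fill(6, 7)                 # F-G-x-G framework-4 motif
VH_FR1 = _fill(21, 1) + "C" + _fill(3, 9)     # 25; Cys at index 21, H1 at +4
VH_FR2 = "W" + _fill(13, 2)                   # 14; Trp closes H1
VH_FR3 = "R" + _fill(28, 4) + "C" + "AR"      # 32; K/R closes H2, C-x-x to H3
VH_FR4 = "WGAG" + _fill(6, 8)                 # W-G-x-G framework-4 motif

# Permitted CDR length windows (from the packaged anchor rules).
_CDR_WINDOWS = {"L1": (10, 17), "L2": (7, 7), "L3": (7, 11),
                "H1": (10, 12), "H2": (16, 19), "H3": (3, 25)}

# CDR content alphabets: no C/W/F anywhere (anchor and motif letters),
# and no K/R inside H2 (its terminator letters) so region ends stay
# unambiguous.
_BASE = "ADEGHIKLMNPQRSTVY"
_CDR_ALPHABETS = {
    "L1": _BASE,
    "L2": _BASE,
    "L3": _BASE,
    "H1": _BASE,
    "H2": _BASE.replace("K", "").replace("R", ""),
    "H3": _BASE,
}


def _random_cdr(rng: np.random.Generator, region: str) -> str:
    lo, hi = _CDR_WINDOWS[region]
    length = int(rng.integers(lo, hi + 1))
    alphabet = np.array(list(_CDR_ALPHABETS[region]))
    return "".join(rng.choice(alphabet, size=length))


def generate_fv(seed: int = 0, n: int = 137) -> list[FvRecord]:
    """Generate n anchor-valid Fv records (deterministic in the seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        vl = (VL_FR1 + _random_cdr(rng, "L1") + VL_FR2
              + _random_cdr(rng, "L2") + VL_FR3
              + _random_cdr(rng, "L3") + VL_FR4)
        vh = (VH_FR1 + _random_cdr(rng, "H1") + VH_FR2
              + _random_cdr(rng, "H2") + VH_FR3
              + _random_cdr(rng, "H3") + VH_FR4)
        records.append(FvRecord(id=f"sim_{i + 1:03d}", vh=vh, vl=vl))
    return records


@dataclass
class PlatformSim:
    """Generative spec for one simulated assay."""

    beta: dict[str, float]
    noise: str = "gaussian"            # "gaussian" | "gumbel"
    signal_fraction: float = 0.4       # var(signal) / var(signal + noise)
    loc: float | None = None           # optional output rescale: mean ...
    scale: float | None = None         # ... and sd of the emitted values
    direction: str = "lower_better"
    censor_fraction: float = 0.0
    censor_value: float = 25.0


@dataclass
class SimConfig:
    """Full generative configuration for a synthetic panel."""

    n: int = 137
    seed: int = 0
    platforms: dict[str, PlatformSim] = field(default_factory=dict)


def default_sim_config(n: int = 137, seed: int = 0,
                       platforms: list[str] | None = None) -> SimConfig:
    """The packaged study-shaped defaults: 12 assays, 137 antibodies.

    HIC/SMAC carry a positive aromatic and negative absolute-charge
    effect; the cross/self-interaction assays carry net-positive-charge
    effects; HEK/DSF/ACC-STAB are weak-signal platforms; extreme-value
    (Gumbel) noise is used for the assays whose distributions are skewed.
    """
    specs = {
        "HIC": PlatformSim({"aro": 1.0, "absQ": -0.7}, "gumbel", 0.6,
                           loc=10.0, scale=1.8, censor_fraction=0.1),
        "SMAC": PlatformSim({"aro": 1.0, "absQ": -0.4}, "gumbel", 0.5,
                            loc=9.0, scale=2.0),
        "CIC": PlatformSim({"aro": 0.6, "PmN": 0.8}, "gumbel", 0.4,
                           loc=1.0, scale=0.5),
        "ACSINS": PlatformSim({"absQ": 0.8, "PmN": 0.6}, "gumbel", 0.4,
                              loc=5.0, scale=3.0),
        "ELISA": PlatformSim({"PmN": 1.0}, "gaussian", 0.45,
                             loc=1.5, scale=0.8),
        "BVP": PlatformSim({"PmN": 1.0, "aro": 0.3}, "gaussian", 0.45,
                           loc=2.0, scale=1.0),
        "SGAC-SINS": PlatformSim({"aro": -0.8, "absQ": 0.5}, "gaussian",
                                 0.35, loc=700.0, scale=150.0,
                                 direction="higher_better"),
        "PSR": PlatformSim({"PmN": 0.9, "aro": 0.3}, "gaussian", 0.4,
                           loc=0.15, scale=0.1),
        "HEK": PlatformSim({"length": 0.3, "pI": 0.4}, "gaussian", 0.15,
                           loc=200.0, scale=60.0,
                           direction="higher_better"),
        "DSF": PlatformSim({"bet": 0.5, "fld": 0.5}, "gaussian", 0.15,
                           loc=70.0, scale=4.0, direction="higher_better"),
        "CSI": PlatformSim({"absQ": 0.7, "PmN": 0.5}, "gumbel", 0.3,
                           loc=0.2, scale=0.3),
        "ACC-STAB": PlatformSim({"mem": 0.4, "aro": 0.3}, "gaussian", 0.15,
                                loc=1.0, scale=0.5),
    }
    if platforms is not None:
        specs = {p: specs[p] for p in platforms}
    return SimConfig(n=n, seed=seed, platforms=specs)


def _draw_noise(rng: np.random.Generator, family: str, sd: float,
                n: int) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    if family == "gaussian":
        return rng.normal(0.0, sd, n)
    if family == "gumbel":
        # centered Gumbel with the requested sd
        beta = sd * np.sqrt(6.0) / np.pi
        draws = rng.gumbel(0.0, beta, n)
        return draws - beta * _EULER_GAMMA
    raise ValueError(f"unknown noise family {family!r}")


def generate_responses(records: list[FvRecord], config: SimConfig) -> Dataset:
    """Simulate the measurement table for a list of records.

    Per platform: y = sum_f beta_f * feature_f + noise, rescaled to the
    spec's (loc, scale); the top ``censor_fraction`` of values (after
    rescaling) is replaced by the censor sentinel.
    """
    if not config.platforms:
        raise DegenerateDataError("SimConfig has no platforms")
    features = feature_table(records)
    rng = np.random.default_rng(config.seed)
    n = len(records)
    columns = {}
    provenance = {"seed": config.seed, "n": n, "platforms": {}}
    for pid, spec in config.platforms.items():
        missing = set(spec.beta) - set(features.columns)
        if missing:
            raise KeyError(f"{pid}: unknown features in beta: {missing}")
        signal = sum(b * features[f] for f, b in spec.beta.items())
        signal = np.asarray(signal, dtype=float)
        var_s = float(np.var(signal, ddof=1)) if n > 1 else 0.0
        sf = spec.signal_fraction
        if not 0 < sf <= 1:
            raise ValueError(f"{pid}: signal_fraction must be in (0, 1]")
        if var_s <= 0 and sf == 1:
            raise DegenerateDataError(
                f"{pid}: zero signal variance and no noise"
            )
        noise_sd = np.sqrt(var_s * (1 - sf) / sf) if sf < 1 else 0.0
        y = signal + _draw_noise(rng, spec.noise, noise_sd, n)
        realized = (var_s / float(np.var(y, ddof=1))
                    if np.var(y, ddof=1) > 0 else 1.0)
        if spec.scale is not None:
            # affine map to the assay's output range (preserves correlations)
            y_sd = float(np.std(y, ddof=1))
            loc = spec.loc if spec.loc is not None else 0.0
            y = (loc + spec.scale * (y - y.mean()) / y_sd if y_sd > 0
                 else np.full(n, loc))
        n_censored = 0
        if spec.censor_fraction > 0:
            k = int(round(spec.censor_fraction * n))
            if k > 0:
                worst = np.argsort(y)[-k:]
                y[worst] = spec.censor_value
                n_censored = k
        columns[pid] = y
        provenance["platforms"][pid] = {
            "beta": dict(spec.beta),
            "noise": spec.noise,
            "signal_fraction": sf,
            "realized_signal_fraction": realized,
            "direction": spec.direction,
            "n_censored": n_censored,
        }
    measurements = pd.DataFrame(columns, index=[r.id for r in records])
    measurements.index.name = "id"
    return Dataset(records=list(records), measurements=measurements,
                   provenance=provenance)


def simulate_dataset(n: int = 137, seed: int = 0,
                     platforms: list[str] | None = None,
                     config: SimConfig | None = None) -> Dataset:
    """One-call generator: anchor-valid sequences + simulated responses."""
    if config is None:
        config = default_sim_config(n=n, seed=seed, platforms=platforms)
    records = generate_fv(seed=config.seed, n=config.n)
    for rec in records:       # construction contract: rules hold by design
        find_cdrs(rec.vh, rec.vl)
    return generate_responses(records, config)
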