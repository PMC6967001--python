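"""The 35-component sequence feature vector for an Fv.

Components, in canonical order:

* ``f_A`` .. ``f_Y`` — the 20 amino-acid composition fractions
  (count / length), alphabetical by one-letter code;
* seven charge/aromatic composites on the composition-fraction scale:
  ``KmR`` = f_K − f_R, ``DmE`` = f_D − f_E, ``KpR`` = f_K + f_R,
  ``DpE`` = f_D + f_E, ``PmN`` = f_K + f_R − f_D − f_E,
  ``PpN`` = f_K + f_R + f_D + f_E, ``aro`` = f_F + f_W + f_Y;
* eight physicochemical summaries: ``fld`` (mean folding propensity),
  ``dis`` (mean disorder propensity), ``bet`` (mean beta-strand propensity),
  ``mem`` (mean Kyte–Doolittle hydropathy), ``pI`` (isoelectric point),
  ``absQ`` = \\|f_K + f_R − f_D − f_E\\| (per-residue absolute net charge;
  histidine excluded), ``entropy`` (Shannon entropy of the 20-letter
  composition, bits), and ``length`` (residue count).
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd

from .cdr import find_cdrs
from .config import AMINO_ACIDS, load_scales
from .errors import SequenceError

COMPOSITION_NAMES = tuple(f"f_{aa}" for aa in AMINO_ACIDS)
COMPOSITE_NAMES = ("KmR", "DmE", "KpR", "DpE", "PmN", "PpN", "aro")
PHYSCHEM_NAMES = ("fld", "dis", "bet", "mem", "pI", "absQ", "entropy",
                  "length")

#: Canonical order of the 35 feature components.
FEATURE_NAMES: tuple[str, ...] = (
    COMPOSITION_NAMES + COMPOSITE_NAMES + PHYSCHEM_NAMES
)


def _check_sequence(fv: str) -> str:
    fv = fv.strip().upper()
    if not fv:
        raise SequenceError("cannot featurize an empty sequence")
    bad = set(fv) - set(AMINO_ACIDS)
    if bad:
        raise SequenceError(
            f"non-canonical amino-acid letters: {sorted(bad)}"
        )
    return fv


def net_charge(fv: str, ph: float, pka: dict | None = None,
               include_termini: bool = True) -> float:
    """Modelled net charge of the sequence at a given pH.

    Henderson–Hasselbalch over the titratable side chains (D, E, C, Y
    acid-side; H, K, R base-side) plus, by default, the free N/C termini.
    """
    if pka is None:
        pka = load_scales()["pka"]
    counts = Counter(fv)
    pos = neg = 0.0
    if include_termini:
        pos += 10 ** -ph / (10 ** -ph + 10 ** -pka["n_term"])
        neg += 10 ** -pka["c_term"] / (10 ** -ph + 10 ** -pka["c_term"])
    for aa in "HKR":
        if aa in pka:
            pos += counts[aa] * 10 ** -ph / (10 ** -ph + 10 ** -pka[aa])
    for aa in "DECY":
        if aa in pka:
            neg += counts[aa] * 10 ** -pka[aa] / (10 ** -ph + 10 ** -pka[aa])
    return pos - neg


def compute_pI(fv: str, tol: float = 1e-4,
               include_termini: bool = True) -> float:
    """Isoelectric point: pH at which the modelled net charge vanishes.

    The charge curve is monotone non-increasing in pH, so plain bisection
    on (0, 14) converges; iteration stops when \\|charge\\| < ``tol``.
    With the termini excluded, a sequence carrying no titratable group has
    no root; the defined fallback is 7.0 (with a warning).
    """
    fv = _check_sequence(fv)
    pka = load_scales()["pka"]
    if not include_termini and not (set(fv) & set("DECYHKR")):
        warnings.warn("no titratable groups: pI undefined, returning 7.0",
                      stacklevel=2)
        return 7.0
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(fv, mid, pka, include_termini=include_termini)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def featurize(fv: str) -> pd.Series:
    """Compute the 35-component feature vector for one Fv sequence."""
    fv = _check_sequence(fv)
    n = len(fv)
    counts = Counter(fv)
    scales = load_scales()

    values: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        values[f"f_{aa}"] = counts[aa] / n

    fK, fR = values["f_K"], values["f_R"]
    fD, fE = values["f_D"], values["f_E"]
    values["KmR"] = fK - fR
    values["DmE"] = fD - fE
    values["KpR"] = fK + fR
    values["DpE"] = fD + fE
    values["PmN"] = fK + fR - fD - fE
    values["PpN"] = fK + fR + fD + fE
    values["aro"] = values["f_F"] + values["f_W"] + values["f_Y"]

    for name in ("fld", "dis", "bet", "mem"):
        table = scales[name]
        values[name] = sum(counts[aa] * table[aa] for aa in counts) / n

    values["pI"] = compute_pI(fv)
    values["absQ"] = abs(fK + fR - fD - fE)
    fracs = np.array([counts[aa] / n for aa in AMINO_ACIDS if counts[aa] > 0])
    values["entropy"] = float(-(fracs * np.log2(fracs)).sum())
    values["length"] = float(n)

    return pd.Series([values[k] for k in FEATURE_NAMES], index=FEATURE_NAMES,
                     dtype=float)


def featurize_regions(vh: str, vl: str) -> dict[str, pd.Series]:
    """Feature vectors for the full Fv and for the concatenated CDRs."""
    cdrs = find_cdrs(vh, vl)
    return {
        "full_fv": featurize(vh + vl),
        "cdrs_concat": featurize(cdrs.concatenated()),
    }


def feature_table(records) -> pd.DataFrame:
    """35-column feature matrix for a list of FvRecords, indexed by id."""
    rows = {rec.id: featurize(rec.fv) for rec in records}
    return pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]
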