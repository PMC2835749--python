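"""Trait preparation: migration coding, brain volume/mass handling,
residual brain size, binarization for the discrete analyses, and
measurement repeatability.

Conventions
-----------
* Endocranial volume converts to mass with the fresh-brain-tissue density
  1.036 g/ml; when both a volume and a literature mass are present the mass
  takes precedence and the volume is only converted where mass is absent.
* Migratory distance is an ordinal 0-4 scale of the shortest seasonal
  movement: 0 none, 1 altitudinal/local (< 100 km), 2 [100, 700) km,
  3 [700, 1500) km, 4 >= 1500 km.  Lower bounds are inclusive.
* "Migratory" as a binary state means movements over 100 km, i.e.
  category >= 2; "large brain" means a positive residual from the ordinary
  log-log regression of brain mass on body mass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BRAIN_TISSUE_DENSITY_G_PER_ML = 1.036

#: recognized trait-table columns (besides ``species``); all optional except
#: body_mass_g and at least one of brain_volume_ml / brain_mass_g
TRAIT_COLUMNS = [
    "brain_volume_ml",
    "brain_mass_g",
    "body_mass_g",
    "migration_category",
    "migration_distance_km",
    "latitude_deg",
    "insectivore",
    "frugivore",
    "forest",
    "monogamous",
    "incubation_d",
    "fledging_d",
    "bmr_kcal_d",
    "sex",
    "family",
]

_BINARY_COLUMNS = ("insectivore", "frugivore", "forest", "monogamous")


@dataclass
class BinaryTraitPair:
    species: str
    brain_large: int
    migratory: int


def volume_to_mass(volume_ml):
    """Convert endocranial volume (ml) to brain mass (g) at fresh-tissue
    density 1.036 g/ml."""
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v < 0):
        raise ValueError("brain volume must be non-negative")
    out = v * BRAIN_TISSUE_DENSITY_G_PER_ML
    return float(out) if np.isscalar(volume_ml) else out


def code_migration_distance(shortest_distance_km: float,
                            altitudinal_or_local: bool = False) -> int:
    """Ordinal migration category from the shortest seasonal movement.

    ``altitudinal_or_local`` marks species whose only movements are
    altitudinal or otherwise local; these are category 1 regardless of a
    (sub-100 km) distance.  A distance of 0 with no local movements is a
    resident (category 0).
    """
    d = float(shortest_distance_km)
    if d < 0:
        raise ValueError("migratory distance must be non-negative")
    if d >= 1500:
        return 4
    if d >= 700:
        return 3
    if d >= 100:
        return 2
    if altitudinal_or_local or d > 0:
        return 1
    return 0


def residual_brain_size(table: pd.DataFrame) -> pd.Series:
    """Residuals of the ordinary least-squares log-log regression of brain
    mass on body mass (one value per species, indexed by species).

    This is the non-phylogenetic allometric correction whose sign defines
    the binary "large brain" state.  Rows lacking brain or body mass are
    dropped (the caller sees this in the returned index).
    """
    t = effective_brain_mass(table)
    t = t.dropna(subset=["brain_mass_g", "body_mass_g"])
    if len(t) < 3:
        raise ValueError("need at least 3 species with brain and body mass")
    if (t["brain_mass_g"] <= 0).any() or (t["body_mass_g"] <= 0).any():
        bad = t.loc[(t["brain_mass_g"] <= 0) | (t["body_mass_g"] <= 0), "species"]
        raise ValueError(f"non-positive masses for: {list(bad)}")
    x = np.log(t["body_mass_g"].to_numpy())
    y = np.log(t["brain_mass_g"].to_numpy())
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return pd.Series(resid, index=pd.Index(t["species"], name="species"),
                     name="brain_residual")


def effective_brain_mass(table: pd.DataFrame) -> pd.DataFrame:
    """Resolve brain mass per species: literature mass where present,
    density-converted endocranial volume otherwise."""
    t = table.copy()
    if "brain_mass_g" not in t:
        t["brain_mass_g"] = np.nan
    if "brain_volume_ml" in t:
        need = t["brain_mass_g"].isna() & t["brain_volume_ml"].notna()
        t.loc[need, "brain_mass_g"] = volume_to_mass(
            t.loc[need, "brain_volume_ml"].to_numpy()
        )
    return t


def binarize(table: pd.DataFrame, residuals: pd.Series) -> list[BinaryTraitPair]:
    """Binary (brain_large, migratory) pair per species.

    brain_large = 1 iff the brain residual is strictly positive (exact zeros
    are coded 0 with a warning); migratory = 1 iff migration_category >= 2,
    i.e. seasonal movements over 100 km.
    """
    t = table.set_index("species")
    out: list[BinaryTraitPair] = []
    n_zero = 0
    for sp, r in residuals.items():
        if sp not in t.index:
            raise KeyError(f"residual for unknown species {sp!r}")
        cat = int(t.loc[sp, "migration_category"])
        if r == 0.0:
            n_zero += 1
        out.append(BinaryTraitPair(species=str(sp),
                                   brain_large=int(r > 0),
                                   migratory=int(cat >= 2)))
    if n_zero:
        warnings.warn(
            f"{n_zero} species had an exactly-zero brain residual; coded as "
            "brain_large=0", stacklevel=2)
    return out


def repeatability(measurements: dict[str, "np.ndarray | list[float]"]) -> float:
    """Among-species variance component (% of total) from a one-way
    random-effects ANOVA on per-specimen measurements grouped by species.

    Negative variance-component estimates are truncated at zero.  When every
    value is identical (total variance zero) the repeatability is 100% by
    convention.
    """
    groups = [np.asarray(v, dtype=float) for v in measurements.values()]
    if len(groups) < 2:
        raise ValueError("repeatability needs at least 2 species")
    if any(len(g) == 0 for g in groups):
        raise ValueError("each species needs at least 1 measurement")
    allv = np.concatenate(groups)
    if np.allclose(allv, allv[0]):
        return 100.0
    k = len(groups)
    N = len(allv)
    grand = allv.mean()
    ss_among = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_among = k - 1
    df_within = N - k
    ms_among = ss_among / df_among
    if df_within == 0:  # one specimen everywhere: all variance is among
        return 100.0
    ms_within = ss_within / df_within
    n0 = (N - sum(len(g) ** 2 for g in groups) / N) / (k - 1)
    s2_among = max((ms_among - ms_within) / n0, 0.0)
    s2_within = ms_within
    total = s2_among + s2_within
    if total == 0:
        return 100.0
    return 100.0 * s2_among / total


def read_trait_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a per-species trait table (CSV or TSV).

    Missing values are empty fields.  Raises on duplicate species, unknown
    migration codes and non-numeric masses; per-column missingness is
    logged at INFO level.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip() for c in df.columns]
    if "species" not in df.columns:
        raise ValueError("trait table needs a 'species' column")
    return validate_trait_table(df)


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    dup = df["species"][df["species"].duplicated()]
    if "sex" in df.columns:
        dup = df[df.duplicated(subset=["species", "sex"])]["species"]
    if len(dup):
        raise ValueError(f"duplicated species rows: {sorted(set(dup))}")
    numeric = [c for c in TRAIT_COLUMNS if c not in ("sex", "family")]
    for c in numeric:
        if c in df.columns:
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"non-numeric values in column {c!r}: {exc}") from exc
    if "migration_category" in df.columns:
        cats = df["migration_category"].dropna()
        bad = cats[~cats.isin([0, 1, 2, 3, 4])]
        if len(bad):
            raise ValueError(f"unknown migration codes: {sorted(set(bad))}")
    if "sex" in df.columns:
        bad_sex = set(df["sex"].dropna()) - {"male", "female", "unknown"}
        if bad_sex:
            raise ValueError(f"unknown sex codes: {sorted(bad_sex)}")
    for c in df.columns:
        n_miss = int(df[c].isna().sum())
        if n_miss:
            logger.info("column %s: %d missing values", c, n_miss)
    return df
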