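"""Synthetic fire landscapes, virtual species, and trait observations.

Every generator here has a known ground truth so that the downstream
stages — occurrence cleaning, fire-frequency estimation, strategy
classification and the trait-environment models — can be verified by
closed-form oracles and parameter recovery instead of real downloads.

The generative model mirrors the analysis assumptions:

* fires in each cell follow a homogeneous Poisson process with annual
  rate r(c), so a cell's event count over a window of T years is
  Poisson(r(c) * T) with event times uniform on the window;
* virtual species occupy contiguous blocks of cells, and their true mean
  fire frequency F is the mean of 100 * r(c) over occupied cells
  (fires per century);
* binary fire-response traits are drawn from a logistic-quadratic curve
  in x = log10(F); observation-level noise is a symmetric label flip,
  which exercises the >=30 %-of-observations classification rule;
* numeric leaf traits are lognormal around group means on the log10 scale.

All generators are pure functions of their inputs and a seed; independent
random streams per operation are derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .grid import FireEventRaster, LandscapeSpec

__all__ = [
    "ResponseCurve",
    "SyntheticTruth",
    "gradient_rate_field",
    "simulate_fire_history",
    "simulate_species_ranges",
    "assign_fire_traits",
    "assign_leaf_traits",
    "inject_contaminants",
    "CONTAMINATION_REASONS",
]


@dataclasses.dataclass(frozen=True)
class ResponseCurve:
    """Logit-scale quadratic response curve p(x) with x = log10(fires per century)."""

    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0

    def probability(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        eta = self.beta0 + self.beta1 * x + self.beta2 * x**2
        return 1.0 / (1.0 + np.exp(-eta))


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated dataset.

    Attributes
    ----------
    species : pandas.DataFrame
        One row per species: ``species``, ``true_rate`` (mean annual rate over
        occupied cells), ``true_F`` (fires per century = 100 * true_rate), and,
        once traits are assigned, ``p_<trait>`` and ``latent_<trait>`` columns.
    occupancy : pandas.DataFrame
        Columns ``species``, ``row``, ``col`` — the occupied cells.
    contamination : pandas.DataFrame
        Columns ``record_id``, ``reason`` for records that the cleaning stage
        should remove; clean records are absent.
    """

    species: pd.DataFrame
    occupancy: pd.DataFrame
    contamination: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame({"record_id": [], "reason": []})
    )


def _validate_rates(spec: LandscapeSpec, rates: np.ndarray) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (spec.n_rows, spec.n_cols):
        raise ValueError(f"rate field shape {rates.shape} does not match grid "
                         f"({spec.n_rows}, {spec.n_cols})")
    if not np.all(np.isfinite(rates)) or (rates < 0).any():
        raise ValueError("rates must be finite and non-negative")
    return rates


def gradient_rate_field(spec: LandscapeSpec, low: float = 0.002, high: float = 0.5) -> np.ndarray:
    """Annual fire rates varying log-smoothly along the column axis.

    A monotone spatial gradient gives species niches a wide fire-frequency
    spectrum (roughly 0.2 to 50 fires per century at the defaults — similar
    in span to observed continental gradients, truncated below so that the
    modest synthetic ranges still accumulate a usable number of events).
    """
    if low <= 0 or high <= 0:
        raise ValueError("rate bounds must be positive")
    cols = np.linspace(np.log10(low), np.log10(high), spec.n_cols)
    return np.tile(10.0**cols, (spec.n_rows, 1))


def simulate_fire_history(spec: LandscapeSpec, rates: np.ndarray, seed: int) -> FireEventRaster:
    """Simulate a fire-event raster from per-cell annual rates.

    Each cell's event count is Poisson(r(c) * T); event times are i.i.d.
    uniform on the window and sorted. Same seed, same output.
    """
    rates = _validate_rates(spec, rates)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF17E]))
    T = spec.window_years
    counts = rng.poisson(rates * T)
    n_total = int(counts.sum())
    rows, cols = np.nonzero(counts)
    reps = counts[rows, cols]
    ev_rows = np.repeat(rows, reps)
    ev_cols = np.repeat(cols, reps)
    times = rng.uniform(spec.window_start, spec.window_end, size=n_total)
    events = pd.DataFrame({"row": ev_rows, "col": ev_cols, "time": times})
    return FireEventRaster(spec, events)


def simulate_species_ranges(
    spec: LandscapeSpec,
    rates: np.ndarray,
    n_species: int,
    seed: int,
    block_rows: int = 6,
    block_cols: int = 8,
    n_occurrences: int = 50,
    year_range: tuple[int, int] = (1950, 2022),
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Place virtual species on the grid and emit occurrence records.

    Each species occupies one contiguous ``block_rows x block_cols`` block of
    cells at a uniformly random position; occurrence points are jittered
    uniformly within randomly chosen occupied cells. The truth ledger records
    the occupied cells and the occupied-cell mean rate (true F = 100 * mean r).

    Returns a Darwin-Core-style occurrence table (``record_id``, ``species``,
    ``decimalLongitude``, ``decimalLatitude``, ``year``, ``basisOfRecord``,
    ``coordinateUncertaintyInMeters``, ``issue``) and the :class:`SyntheticTruth`.
    """
    rates = _validate_rates(spec, rates)
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if block_rows > spec.n_rows or block_cols > spec.n_cols:
        raise ValueError("species range block larger than the grid")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5BEC]))

    names = [f"sp{i:05d}" for i in range(n_species)]
    top = rng.integers(0, spec.n_rows - block_rows + 1, size=n_species)
    left = rng.integers(0, spec.n_cols - block_cols + 1, size=n_species)

    br = np.arange(block_rows)[None, :, None]
    bc = np.arange(block_cols)[None, None, :]
    occ_rows = np.broadcast_to(top[:, None, None] + br,
                               (n_species, block_rows, block_cols)).reshape(n_species, -1)
    occ_cols = np.broadcast_to(left[:, None, None] + bc,
                               (n_species, block_rows, block_cols)).reshape(n_species, -1)
    n_block = block_rows * block_cols
    occupancy = pd.DataFrame({
        "species": np.repeat(names, n_block),
        "row": occ_rows.ravel(),
        "col": occ_cols.ravel(),
    })
    true_rate = rates[occ_rows, occ_cols].mean(axis=1)
    species = pd.DataFrame({
        "species": names,
        "true_rate": true_rate,
        "true_F": 100.0 * true_rate,
    })

    # occurrence points: pick occupied cells with replacement, jitter in-cell
    pick = rng.integers(0, n_block, size=(n_species, n_occurrences))
    sel = np.arange(n_species)[:, None]
    prow = occ_rows[sel, pick].ravel()
    pcol = occ_cols[sel, pick].ravel()
    jitter = rng.uniform(0, spec.cell_size, size=(2, n_species * n_occurrences))
    lon = spec.origin[0] + pcol * spec.cell_size + jitter[0]
    lat = spec.origin[1] + prow * spec.cell_size + jitter[1]
    n_rec = n_species * n_occurrences
    occurrences = pd.DataFrame({
        "record_id": np.arange(n_rec),
        "species": np.repeat(names, n_occurrences),
        "decimalLongitude": lon,
        "decimalLatitude": lat,
        "year": rng.integers(year_range[0], year_range[1] + 1, size=n_rec),
        "basisOfRecord": rng.choice(
            ["HUMAN_OBSERVATION", "PRESERVED_SPECIMEN", "LIVING_SPECIMEN"], size=n_rec
        ),
        "coordinateUncertaintyInMeters": rng.uniform(5, 5000, size=n_rec).round(0),
        "issue": "",
    })
    return occurrences, SyntheticTruth(species=species, occupancy=occupancy)


def assign_fire_traits(
    truth: SyntheticTruth,
    resprout_curve: ResponseCurve,
    seed_curve: ResponseCurve,
    n_obs_per_species: int,
    flip_prob: float,
    seed: int,
    one_sided_flip: bool = False,
) -> pd.DataFrame:
    """Draw latent fire-response labels from the response curves and emit
    noisy long-format observations.

    For each species with true F > 0, x = log10(F); the latent resprouter /
    seeder labels are Bernoulli(p) with p = logistic(b0 + b1 x + b2 x^2).
    Each of the ``n_obs_per_species`` categorical observations is flipped
    with probability ``flip_prob`` (symmetric by default; with
    ``one_sided_flip`` only positive observations flip, emulating the
    harder detection of absence).

    Mutates ``truth.species`` in place, adding ``p_resprout``, ``p_seed``,
    ``latent_resprout`` and ``latent_seed`` columns, and returns the trait
    observation table (``taxon``, ``trait``, ``value``, ``source``).
    """
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    sp = truth.species
    if (sp["true_F"] <= 0).any():
        raise ValueError("all species must have true F > 0 for log10 transform")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7A17]))
    x = np.log10(sp["true_F"].to_numpy())
    n = len(sp)
    frames = []
    for trait, curve, pos, neg in [
        ("resprouting_capacity", resprout_curve, "resprouts", "fire_killed"),
        ("post_fire_recruitment", seed_curve, "post_fire_recruitment", "no_post_fire_recruitment"),
    ]:
        p = curve.probability(x)
        latent = rng.random(n) < p
        key = "resprout" if trait == "resprouting_capacity" else "seed"
        sp[f"p_{key}"] = p
        sp[f"latent_{key}"] = latent
        obs = np.repeat(latent, n_obs_per_species)
        flips = rng.random(n * n_obs_per_species) < flip_prob
        if one_sided_flip:
            flips &= obs
        obs = obs ^ flips
        frames.append(pd.DataFrame({
            "taxon": np.repeat(sp["species"].to_numpy(), n_obs_per_species),
            "trait": trait,
            "value": np.where(obs, pos, neg),
            # distinct source per observation: repeated observations of a
            # species are independent records, not one duplicated row
            "source": np.tile([f"synthetic_{j}" for j in range(n_obs_per_species)], n),
        }))
    return pd.concat(frames, ignore_index=True)


def assign_leaf_traits(
    profiles: pd.DataFrame,
    effects: dict[str, float],
    sd: float,
    seed: int,
    trait: str = "leaf_mass_per_area",
    group_col: str = "group",
    n_rows_per_species: int = 1,
) -> pd.DataFrame:
    """Emit numeric trait rows with log10(value) ~ Normal(group mean, sd).

    ``profiles`` needs columns ``taxon`` and ``group_col``; ``effects`` maps
    each group label to its mean on the log10 scale. Multiple rows per
    species are allowed (they exercise the row-mean rule downstream).
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    missing = set(profiles[group_col]) - set(effects)
    if missing:
        raise ValueError(f"no effect specified for groups: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1EAF]))
    mu = profiles[group_col].map(effects).to_numpy(dtype=float)
    mu = np.repeat(mu, n_rows_per_species)
    taxa = np.repeat(profiles["taxon"].to_numpy(), n_rows_per_species)
    log_vals = rng.normal(mu, sd) if sd > 0 else mu.copy()
    return pd.DataFrame({
        "taxon": taxa,
        "trait": trait,
        "value": 10.0**log_vals,
        "source": "synthetic",
    })


# reason codes the cleaning stage knows how to remove; the injector can
# fabricate a record violating each one
CONTAMINATION_REASONS = (
    "not_georeferenced",
    "basis_of_record",
    "pre_1900",
    "zero_coordinate",
    "out_of_bounds",
    "low_precision",
    "high_uncertainty",
    "issue_flag",
    "duplicate",
)


def inject_contaminants(
    occurrences: pd.DataFrame,
    contamination_spec: dict[str, int],
    seed: int,
    truth: SyntheticTruth | None = None,
) -> pd.DataFrame:
    """Append labelled dirty records that the cleaning filters should catch.

    ``contamination_spec`` maps reason codes (a subset of
    :data:`CONTAMINATION_REASONS`) to the number of records to fabricate for
    that reason. Each fabricated record is a copy of a random clean record
    modified to violate exactly that filter; duplicates are exact copies.
    Labels are recorded in ``truth.contamination`` when a truth is given.
    An empty spec returns the input unchanged.
    """
    unknown = set(contamination_spec) - set(CONTAMINATION_REASONS)
    if unknown:
        raise ValueError(f"unknown contamination reasons: {sorted(unknown)}")
    if not contamination_spec:
        return occurrences
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD127]))
    out = occurrences.copy()
    next_id = int(out["record_id"].max()) + 1 if len(out) else 0
    new_rows, labels = [], []
    for reason, count in contamination_spec.items():
        for _ in range(int(count)):
            # sample bases from the clean input only, so each fabricated
            # record violates exactly its intended filter
            base = occurrences.iloc[int(rng.integers(0, len(occurrences)))].copy()
            # duplicates keep all data columns but still get a fresh id so the
            # removal (the later copy) is attributable
            base["record_id"] = next_id
            next_id += 1
            if reason == "not_georeferenced":
                base["decimalLongitude"] = np.nan
                base["decimalLatitude"] = np.nan
            elif reason == "basis_of_record":
                base["basisOfRecord"] = "FOSSIL_SPECIMEN"
            elif reason == "pre_1900":
                base["year"] = int(rng.integers(1800, 1901))
            elif reason == "zero_coordinate":
                base["decimalLongitude" if rng.random() < 0.5 else "decimalLatitude"] = 0.0
            elif reason == "out_of_bounds":
                base["decimalLatitude"] = 91.0 + float(rng.random())
            elif reason == "low_precision":
                base["decimalLongitude"] = round(float(base["decimalLongitude"]), 1)
                base["decimalLatitude"] = round(float(base["decimalLatitude"]), 1)
            elif reason == "high_uncertainty":
                base["coordinateUncertaintyInMeters"] = float(rng.integers(10001, 50000))
            elif reason == "issue_flag":
                base["issue"] = "COUNTRY_COORDINATE_MISMATCH"
            labels.append({"record_id": int(base["record_id"]), "reason": reason})
            new_rows.append(base)
    out = pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)
    if truth is not None:
        truth.contamination = pd.concat(
            [truth.contamination, pd.DataFrame(labels)], ignore_index=True
        ).astype({"record_id": int})
    return out
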