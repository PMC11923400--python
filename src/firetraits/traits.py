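"""Per-species fire-response strategy, growth form and leaf traits from
long-format trait observations.

Classification rules:

* a taxon is a **resprouter** when at least 30 % of its resprouting
  observations record full or partial resprouting, and a **postfire
  seeder** when at least 30 % of its recruitment observations record
  postfire recruitment (ties at exactly 30 % classify positive);
* **facultative** = resprouter AND seeder, when both are known;
* growth form is derived from woodiness vocabulary values through an
  editable token mapping; taxa with conflicting pure values ("woody" and
  "herbaceous" both observed) are *ambiguous*, and semi-woody / ambiguous
  taxa are flagged for downstream exclusion;
* life history resolves to *perennial* when any observation says
  perennial (a taxon scored both annual and perennial can persist);
* numeric traits (LMA g m^-2, leaf N mg g^-1) are averaged per taxon over
  observation rows, ignoring replicate counts.

Missing data stay missing: a taxon with no observations of a trait is
absent from that trait's denominator, never counted as negative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "RESPROUT_POSITIVE", "RESPROUT_VALUES", "SEED_POSITIVE", "SEED_VALUES",
    "DEFAULT_WOODINESS_MAPPING",
    "classify_resprouting", "classify_seeding", "classify_growth_form",
    "resolve_life_history", "species_mean_numeric_trait",
    "build_profiles", "strategy_summary",
]

RESPROUT_POSITIVE = frozenset({"resprouts", "partial_resprouting"})
RESPROUT_VALUES = RESPROUT_POSITIVE | {"fire_killed"}
SEED_POSITIVE = frozenset({"post_fire_recruitment"})
SEED_VALUES = SEED_POSITIVE | {"no_post_fire_recruitment"}

#: editable value -> group table for woodiness vocabularies. Values not in
#: the table fall back to token logic: only woody tokens -> woody, only
#: herbaceous tokens -> herbaceous, a semi-woody token (alone or with one
#: other) -> semi_woody, woody and herbaceous together -> ambiguous.
DEFAULT_WOODINESS_MAPPING: dict[str, str] = {
    "woody": "woody",
    "herbaceous": "herbaceous",
    "semi_woody": "semi_woody",
    "woody_base": "woody",
    "woody_root": "woody",
    "herbaceous semi_woody": "semi_woody",
    "semi_woody woody": "semi_woody",
    "herbaceous woody": "ambiguous",
}


def _positive_fraction(values: pd.Series, positive: frozenset, vocab: frozenset,
                       trait: str) -> float:
    vals = values.dropna().astype(str)
    if len(vals) == 0:
        raise ValueError(f"no observations of {trait}")
    unknown = set(vals) - set(vocab)
    if unknown:
        raise ValueError(f"unknown {trait} values: {sorted(unknown)}")
    return vals.isin(positive).mean()


def classify_resprouting(values: pd.Series, threshold: float = 0.30) -> bool:
    """True iff >= ``threshold`` of the observations record (partial) resprouting."""
    return bool(_positive_fraction(values, RESPROUT_POSITIVE, RESPROUT_VALUES,
                                   "resprouting_capacity") >= threshold)


def classify_seeding(values: pd.Series, threshold: float = 0.30) -> bool:
    """True iff >= ``threshold`` of the observations record postfire recruitment."""
    return bool(_positive_fraction(values, SEED_POSITIVE, SEED_VALUES,
                                   "post_fire_recruitment") >= threshold)


def _woodiness_group(value: str, mapping: dict[str, str]) -> str:
    v = str(value).strip()
    if v in mapping:
        return mapping[v]
    tokens = set(v.replace("semi_woody", "SEMI").split())
    kinds = set()
    for tok in tokens:
        if tok == "SEMI":
            kinds.add("semi")
        elif "woody" in tok:
            kinds.add("woody")
        elif "herb" in tok:
            kinds.add("herbaceous")
        else:
            raise ValueError(f"unmapped woodiness value: {value!r}")
    if kinds == {"woody"}:
        return "woody"
    if kinds == {"herbaceous"}:
        return "herbaceous"
    if "woody" in kinds and "herbaceous" in kinds:
        return "ambiguous"
    return "semi_woody"


def classify_growth_form(
    values: pd.Series, mapping: dict[str, str] | None = None
) -> str:
    """Growth-form group for one taxon from its woodiness values.

    Per-value groups come from ``mapping`` (default
    :data:`DEFAULT_WOODINESS_MAPPING`) with token fallback; the taxon group
    is the unanimous per-value group, *ambiguous* when woody and herbaceous
    both occur or any value is itself ambiguous.
    """
    mapping = DEFAULT_WOODINESS_MAPPING if mapping is None else mapping
    groups = {_woodiness_group(v, mapping) for v in values.dropna()}
    if not groups:
        raise ValueError("no woodiness observations")
    if len(groups) == 1:
        return next(iter(groups))
    if "ambiguous" in groups or {"woody", "herbaceous"} <= groups:
        return "ambiguous"
    # semi_woody mixed with a single pure form stays semi_woody
    return "semi_woody"


def resolve_life_history(values: pd.Series) -> str:
    """Perennial if any value is perennial; annual only when all are annual."""
    vals = set(values.dropna().astype(str))
    if not vals:
        raise ValueError("no life-history observations")
    unknown = vals - {"annual", "perennial"}
    if unknown:
        raise ValueError(f"unknown life-history values: {sorted(unknown)}")
    return "perennial" if "perennial" in vals else "annual"


def species_mean_numeric_trait(rows: pd.Series) -> float:
    """Unweighted arithmetic mean over observation rows (replicates ignored)."""
    vals = pd.to_numeric(rows, errors="raise").dropna()
    if len(vals) == 0:
        raise ValueError("no numeric observations")
    bad = vals[vals <= 0]
    if len(bad):
        raise ValueError(f"non-positive trait values at rows {list(bad.index)}")
    return float(vals.mean())


def build_profiles(
    observations: pd.DataFrame,
    threshold: float = 0.30,
    woodiness_mapping: dict[str, str] | None = None,
    drop_infraspecific: bool = False,
) -> pd.DataFrame:
    """Aggregate a long-format observation table into one profile per taxon.

    ``observations`` columns: ``taxon``, ``trait``, ``value``, ``source``
    (optional). Recognised traits: ``resprouting_capacity``,
    ``post_fire_recruitment``, ``woodiness``/``woodiness_detailed``,
    ``life_history``, ``leaf_mass_per_area``, ``leaf_N``. Duplicate
    (taxon, trait, value, source) rows are collapsed before categorical
    classification; numeric traits keep every row (the row-mean rule).
    Infraspecific taxa (names with more than two words) can be dropped for
    sensitivity analyses.
    """
    obs = observations.copy()
    if drop_infraspecific:
        obs = obs[obs["taxon"].str.split().str.len() <= 2]
    taxa = pd.Index(sorted(obs["taxon"].unique()), name="taxon")
    prof = pd.DataFrame(index=taxa)

    cat = obs
    if "source" in obs.columns:
        cat = obs.drop_duplicates(["taxon", "trait", "value", "source"])

    def per_taxon(trait_names, func, col):
        sub = cat[cat["trait"].isin(trait_names)]
        if len(sub):
            prof[col] = sub.groupby("taxon")["value"].apply(func)

    per_taxon(["resprouting_capacity"],
              lambda v: classify_resprouting(v, threshold), "resprouter")
    per_taxon(["post_fire_recruitment"],
              lambda v: classify_seeding(v, threshold), "seeder")
    per_taxon(["woodiness", "woodiness_detailed"],
              lambda v: classify_growth_form(v, woodiness_mapping), "growth_form")
    per_taxon(["life_history"], resolve_life_history, "life_history")

    for trait, col in [("leaf_mass_per_area", "mean_lma"), ("leaf_N", "mean_leaf_n")]:
        sub = obs[obs["trait"] == trait]
        if len(sub):
            prof[col] = sub.groupby("taxon")["value"].apply(species_mean_numeric_trait)

    for col in ("resprouter", "seeder", "growth_form", "life_history",
                "mean_lma", "mean_leaf_n"):
        if col not in prof.columns:
            prof[col] = np.nan
    both = prof["resprouter"].notna() & prof["seeder"].notna()
    prof["facultative"] = np.where(
        both, prof["resprouter"].eq(True) & prof["seeder"].eq(True), np.nan
    )
    prof["exclude_growth_form"] = prof["growth_form"].isin(["semi_woody", "ambiguous"])
    return prof.reset_index()


def strategy_summary(
    profiles: pd.DataFrame,
    by: tuple[str, ...] = ("growth_form", "life_history"),
    strategies: tuple[str, ...] = ("resprouter", "seeder"),
) -> pd.DataFrame:
    """Counts and percentages of each strategy within profile groups.

    Denominators are species *with data* for the strategy; percentages are
    rounded to one decimal place.
    """
    rows = []
    for keys, grp in profiles.groupby(list(by), dropna=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for strat in strategies:
            with_data = grp[grp[strat].notna()]
            n = len(with_data)
            k = int(with_data[strat].eq(True).sum())
            rows.append({
                **dict(zip(by, keys)),
                "strategy": strat,
                "n_positive": k,
                "n_with_data": n,
                "percent": round(100.0 * k / n, 1) if n else float("nan"),
            })
    return pd.DataFrame(rows)
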