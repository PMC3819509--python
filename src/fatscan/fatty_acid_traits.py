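"""Fatty-acid trait derivation: bases, composites, indices and summaries.

Intramuscular fatty-acid composition is expressed on two bases:

* **beef basis** — weight of the fatty acid, g x 1e-5, per gram of meat;
* **fat-percent basis** — weight relative to total extracted fatty acid,
  times 100 (a composition closed to 100).

From the 38 individually measured fatty acids, composite traits (MCFA,
LCFA, MUFA, PUFA, SFA, omega-3 and omega-6 sums) and ratio/index traits
(PUFA/SFA, (14:0+16:0)/All, n3/n6 and the Ulbricht–Southgate atherogenic
index) are derived, for 49 analyzed traits per basis.  Ratio and index
traits are reported x100 on the fat-percent basis — the only scale
consistent with the published summary statistics — and are undefined (NA)
on the beef basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# fatty-acid registry: name -> (carbons, double bonds, omega series or None)
# trans isomers count as unsaturated per their bond count; the two conjugated
# linoleic acids (CLA) are 18:2 dienes.
# ---------------------------------------------------------------------------
FATTY_ACIDS: dict[str, tuple[int, int, str | None]] = {
    "10:0": (10, 0, None),
    "12:0": (12, 0, None),
    "13:0": (13, 0, None),
    "14:0": (14, 0, None),
    "14:1": (14, 1, None),
    "15:0": (15, 0, None),
    "16:0": (16, 0, None),
    "16:1": (16, 1, None),
    "17:0": (17, 0, None),
    "17:1": (17, 1, None),
    "18:0": (18, 0, None),
    "cis-9 18:1": (18, 1, None),
    "cis-11 18:1": (18, 1, None),
    "cis-12 18:1": (18, 1, None),
    "cis-13 18:1": (18, 1, None),
    "trans-6/9 18:1": (18, 1, None),
    "trans-10/11 18:1": (18, 1, None),
    "trans-12 18:1": (18, 1, None),
    "trans-15 18:1": (18, 1, None),
    "18:2": (18, 2, "n6"),
    "18:3n3": (18, 3, "n3"),
    "18:3n6": (18, 3, "n6"),
    "20:0": (20, 0, None),
    "20:1": (20, 1, None),
    "20:2": (20, 2, "n6"),
    "20:3n3": (20, 3, "n3"),
    "20:3n6": (20, 3, "n6"),
    "20:4": (20, 4, "n6"),
    "20:5": (20, 5, "n3"),
    "22:0": (22, 0, None),
    "22:1": (22, 1, None),
    "22:4": (22, 4, "n6"),
    "22:5": (22, 5, "n3"),
    "22:6": (22, 6, "n3"),
    "23:0": (23, 0, None),
    "24:0": (24, 0, None),
    "CLAc9t11": (18, 2, "cla"),
    "CLAt10c12": (18, 2, "cla"),
}

SFA_MEMBERS = tuple(n for n, (_, b, _o) in FATTY_ACIDS.items() if b == 0)
MUFA_MEMBERS = tuple(n for n, (_, b, _o) in FATTY_ACIDS.items() if b == 1)
PUFA_MEMBERS = tuple(n for n, (_, b, _o) in FATTY_ACIDS.items() if b >= 2)

#: default MCFA/LCFA split follows the published summary table (carbons
#: 10–15 vs >=16); the stricter text reading (MCFA = 12:0 + 13:0, LCFA =
#: >=14 carbons) is available via ``mcfa="text"``.
MCFA_TABLE1 = tuple(n for n, (c, _b, _o) in FATTY_ACIDS.items() if c <= 15)
LCFA_TABLE1 = tuple(n for n, (c, _b, _o) in FATTY_ACIDS.items() if c >= 16)
MCFA_TEXT = ("12:0", "13:0")
LCFA_TEXT = tuple(n for n, (c, _b, _o) in FATTY_ACIDS.items() if c >= 14)

#: omega-3 sum: full series by default (matches the published n3 mean);
#: the two-term text definition (18:3n3 + 20:3n3) via ``n3="text"``.
N3_FULL = tuple(n for n, (_c, _b, o) in FATTY_ACIDS.items() if o == "n3")
N3_TEXT = ("18:3n3", "20:3n3")
#: omega-6 membership is ambiguous in the source; both options exposed.
N6_NO_CLA = tuple(n for n, (_c, _b, o) in FATTY_ACIDS.items() if o == "n6")
N6_WITH_CLA = N6_NO_CLA + ("CLAc9t11", "CLAt10c12")
N6_TEXT = ("18:3n6", "20:3n6")

RATIO_TRAITS = ("PUFA/SFA", "(14:0+16:0)/All", "AI", "n3/n6")

#: every analyzed trait: 38 singles + 11 composites/ratios
ALL_TRAITS = tuple(FATTY_ACIDS) + (
    "MCFA", "LCFA", "MUFA", "PUFA", "SFA",
    "PUFA/SFA", "(14:0+16:0)/All", "AI", "n3", "n6", "n3/n6",
)


@dataclass(frozen=True)
class TraitDefinition:
    """A derived trait: a named linear combination or ratio of acids."""

    name: str
    members: tuple[str, ...]
    kind: str  # single | sum | ratio | index
    coefficients: tuple[float, ...] | None = None


def default_definitions(mcfa: str = "table1", n3: str = "full",
                        n6: str = "with_cla") -> dict[str, TraitDefinition]:
    """Composite/ratio trait definitions under the configurable memberships."""
    mcfa_m, lcfa_m = (MCFA_TABLE1, LCFA_TABLE1) if mcfa == "table1" else (
        MCFA_TEXT, LCFA_TEXT)
    n3_m = N3_FULL if n3 == "full" else N3_TEXT
    n6_m = {"with_cla": N6_WITH_CLA, "no_cla": N6_NO_CLA, "text": N6_TEXT}[n6]
    defs = {
        "MCFA": TraitDefinition("MCFA", mcfa_m, "sum"),
        "LCFA": TraitDefinition("LCFA", lcfa_m, "sum"),
        "MUFA": TraitDefinition("MUFA", MUFA_MEMBERS, "sum"),
        "PUFA": TraitDefinition("PUFA", PUFA_MEMBERS, "sum"),
        "SFA": TraitDefinition("SFA", SFA_MEMBERS, "sum"),
        "n3": TraitDefinition("n3", n3_m, "sum"),
        "n6": TraitDefinition("n6", n6_m, "sum"),
        "PUFA/SFA": TraitDefinition("PUFA/SFA", ("PUFA", "SFA"), "ratio"),
        "n3/n6": TraitDefinition("n3/n6", ("n3", "n6"), "ratio"),
        "(14:0+16:0)/All": TraitDefinition(
            "(14:0+16:0)/All", ("14:0", "16:0"), "ratio"),
        "AI": TraitDefinition("AI", ("14:0", "16:0"), "index"),
    }
    return defs


def definitions_to_table(defs: dict[str, TraitDefinition]) -> pd.DataFrame:
    rows = [
        {"trait": d.name, "member": m, "coefficient": 1.0, "kind": d.kind}
        for d in defs.values() for m in d.members
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# basis conversion
# ---------------------------------------------------------------------------

def to_fat_percent(profile: pd.DataFrame) -> pd.DataFrame:
    """Close a beef-basis profile to percent of total fatty acid (sum 100).

    ``profile``: rows = animals, columns = fatty-acid names, values >= 0.
    Idempotent up to scale: reapplying returns the same composition.
    """
    vals = profile.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative fatty-acid weights")
    total = vals.sum(axis=1)
    if (total <= 0).any():
        bad = profile.index[total <= 0].tolist()
        raise ValueError(f"all-zero fatty-acid profile for {bad}: "
                         "composition undefined")
    return profile.div(total, axis=0) * 100.0


# ---------------------------------------------------------------------------
# composites and indices
# ---------------------------------------------------------------------------

def atherogenic_index(profile: pd.DataFrame, scale: float = 100.0) -> pd.Series:
    """Ulbricht–Southgate atherogenic index on a fat-percent profile.

    AI = (4*C14:0 + C16:0) / (sum MUFA + sum PUFA), reported x``scale``.
    Zero denominator yields NA.
    """
    num = 4.0 * profile["14:0"] + profile["16:0"]
    den = profile[list(MUFA_MEMBERS)].sum(axis=1) + \
        profile[list(PUFA_MEMBERS)].sum(axis=1)
    out = scale * num / den.replace(0.0, np.nan)
    # all-zero numerator with positive denominator is a genuine 0
    return out.where(den != 0, np.where(num == 0, 0.0, np.nan))


def composite_traits(profile: pd.DataFrame,
                     definitions: dict[str, TraitDefinition] | None = None,
                     basis: str = "fat_percent",
                     ratio_scale: float = 100.0) -> pd.DataFrame:
    """Evaluate composite and ratio traits on a per-animal profile.

    Sum traits are computed on either basis.  Ratio/index traits are only
    meaningful on the closed fat-percent basis, where they are reported
    x``ratio_scale``; on the beef basis they are NA.  A zero denominator
    yields NA.
    """
    defs = definitions or default_definitions()
    out = pd.DataFrame(index=profile.index)
    for name, d in defs.items():
        if d.kind == "sum":
            missing = [m for m in d.members if m not in profile.columns]
            if missing:
                raise KeyError(f"profile lacks members {missing} of {name}")
            out[name] = profile[list(d.members)].sum(axis=1)
    for name, d in defs.items():
        if d.kind == "sum":
            continue
        if basis != "fat_percent":
            out[name] = np.nan
            continue
        if name == "AI":
            out[name] = atherogenic_index(profile, scale=ratio_scale)
        elif name == "(14:0+16:0)/All":
            total = profile[list(FATTY_ACIDS)].sum(axis=1)
            out[name] = ratio_scale * (profile["14:0"] + profile["16:0"]) / \
                total.replace(0.0, np.nan)
        else:  # generic two-member ratio over already-computed sums
            num_name, den_name = d.members
            num = out[num_name] if num_name in out else profile[num_name]
            den = out[den_name] if den_name in out else profile[den_name]
            out[name] = ratio_scale * num / den.replace(0.0, np.nan)
    return out


def derive_traits(profile: pd.DataFrame, basis: str = "fat_percent",
                  definitions: dict[str, TraitDefinition] | None = None
                  ) -> pd.DataFrame:
    """Full 49-trait table: the 38 measured acids plus all composites."""
    singles = profile[[c for c in ALL_TRAITS if c in profile.columns]]
    comps = composite_traits(profile, definitions, basis=basis)
    out = pd.concat([singles, comps], axis=1)
    return out[[t for t in ALL_TRAITS if t in out.columns]]


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summary_stats(traits: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1) and CV x 100 per trait column.

    CV is NA when the mean is zero.  Matches the layout of the published
    per-trait summary table.
    """
    rows = []
    for name in traits.columns:
        v = traits[name].dropna().to_numpy(dtype=float)
        if v.size < 2:
            rows.append({"Trait": name, "mean": np.nan, "SD": np.nan,
                         "CV_x100": np.nan})
            continue
        mu = v.mean()
        sd = v.std(ddof=1)
        cv = 100.0 * sd / mu if mu != 0 else np.nan
        rows.append({"Trait": name, "mean": mu, "SD": sd, "CV_x100": cv})
    return pd.DataFrame(rows)
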