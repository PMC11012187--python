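"""Synthetic inputs with the statistical structure the workflow assumes.

The study's raw abundance tables are not deposited, so every pipeline stage
is exercised on generated data:

* factorial responses — drawn from the published per-subclass coefficient
  models (the 8-term coded basis) plus i.i.d. Gaussian noise on the
  [0, 1]-scaled response scale;
* solvent-screening abundances — three solvent groups (ME = methanol/ethyl
  acetate, EE = ethanol/ethyl acetate, IE = isopropanol/ethyl acetate) where
  ME and IE are well separated and EE sits between them with overlap, and
  the ME-vs-EE relative mean shift stays below 20% per subclass;
* a deterministic lipid identification fixture reproducing the reported
  inventory (449 species, 18 subclass groups, 322 TG with the published
  per-position saturation/chain-length tallies);
* replicate QC injections of deuterated standards with a configurable true
  RSD.

Every generator is a pure function of its configuration including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignTable, build_full_factorial, default_mae_factors, model_matrix
from .ffd_model import ResponseTable

__all__ = [
    "GeneratorConfig",
    "COEFFICIENT_TABLE",
    "RESPONSE_COLUMNS",
    "default_design",
    "gen_ffd_responses",
    "gen_solvent_screening",
    "gen_lipid_fixture",
    "gen_method_comparison_pair",
    "gen_qc_table",
]

# ---------------------------------------------------------------------------
# Generative truth for the factorial responses
# ---------------------------------------------------------------------------

#: published coefficient models on the [0, 1]-scaled response scale;
#: terms absent from a model are exact zeros in the generative truth
COEFFICIENT_TABLE: dict[str, dict[str, float]] = {
    "Cer": {"b0": 0.474, "b1": -0.119, "b2": -0.112, "b23": 0.236},
    "Hex1Cer": {"b0": 0.453, "b2": -0.203, "b23": 0.166, "b123": -0.212},
    "LPC": {"b0": 0.335, "b1": 0.334, "b3": 0.117, "b13": 0.115},
    "LPE": {"b0": 0.428, "b1": 0.344},
    "LPI": {
        "b0": 0.364, "b1": 0.345, "b2": 0.021, "b3": 0.096,
        "b12": 0.034, "b13": 0.096, "b23": -0.072, "b123": -0.081,
    },
    "LPS": {"b0": 0.343, "b1": 0.331, "b3": 0.109, "b13": 0.121, "b123": -0.075},
    "PC": {
        "b0": 0.502, "b1": -0.241, "b2": -0.114, "b3": -0.065,
        "b12": -0.061, "b13": -0.066, "b23": 0.115, "b123": -0.080,
    },
    "PE": {"b0": 0.512, "b1": -0.238, "b2": -0.115, "b3": -0.071, "b23": 0.090, "b123": -0.076},
    "PI": {"b0": 0.425, "b1": -0.286, "b2": -0.131},
    "TG_2OX": {"b0": 0.115, "b1": 0.141, "b3": 0.137},
}

#: intercept-only truth for subclasses with no factor dependence
_NONRESPONSIVE_INTERCEPTS = {
    "TG": 0.52, "TG_1OX": 0.41, "DG": 0.55, "DG_OX": 0.38,
    "ChE": 0.47, "BisMePA": 0.44, "PS": 0.50, "SM": 0.58,
}

#: the 18 response columns (hexosylceramides enter as one column, Hex1Cer)
RESPONSE_COLUMNS = (
    "TG", "TG_1OX", "TG_2OX", "DG", "DG_OX", "ChE", "BisMePA",
    "LPC", "PC", "PE", "LPE", "PI", "LPI", "PS", "LPS", "SM",
    "Cer", "Hex1Cer",
)

_TERM_INDEX = {t: i for i, t in enumerate(("b0", "b1", "b2", "b3", "b12", "b13", "b23", "b123"))}


def coefficient_vector(response: str) -> np.ndarray:
    """Length-8 generative coefficient vector for one response column."""
    beta = np.zeros(8)
    if response in COEFFICIENT_TABLE:
        for term, val in COEFFICIENT_TABLE[response].items():
            beta[_TERM_INDEX[term]] = val
    elif response in _NONRESPONSIVE_INTERCEPTS:
        beta[0] = _NONRESPONSIVE_INTERCEPTS[response]
    else:
        raise KeyError(f"no generative model for response {response!r}")
    return beta


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for all stochastic generators.

    ``noise_sd`` is on the [0, 1]-scaled response scale; 0.01 keeps every
    published effect (|b| 0.02-0.35) clearly above noise at 3 residual
    degrees of freedom, matching the reported significance patterns.
    ``within_group_cv`` is the within-solvent coefficient of variation of
    the screening abundances for ME and IE; the EE replicates are more
    heterogeneous by ``ee_cv_multiplier`` — ethanol/ethyl acetate is the
    solvent whose extractions scatter across clusters and resist
    discrimination, and that behaviour comes from replicate spread, not from
    mean displacement (the EE mean stays within 20% of ME).
    """

    seed: int = 0
    noise_sd: float = 0.01
    n_per_solvent: int = 12
    within_group_cv: float = 0.05
    ee_cv_multiplier: float = 1.6

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_per_solvent < 4:
            raise ValueError("n_per_solvent must be >= 4")
        if self.ee_cv_multiplier < 1:
            raise ValueError("ee_cv_multiplier must be >= 1")


def default_design() -> DesignTable:
    """The 11-run design: 2^3 corners + 3 center replicates at study ranges."""
    return build_full_factorial(default_mae_factors(), n_center=3)


def gen_ffd_responses(design: DesignTable, config: GeneratorConfig = GeneratorConfig()) -> ResponseTable:
    """Responses at the design points from the coefficient models plus noise.

    The output is already on the modelling (scaled) scale — the ``scaled``
    flag is set so the pipeline does not rescale it again.
    """
    if design.k != 3:
        raise ValueError("generator needs a 3-factor design")
    X = model_matrix(design)
    rng = np.random.default_rng(config.seed)
    data = {}
    for col in RESPONSE_COLUMNS:
        y = X @ coefficient_vector(col)
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=len(y))
        data[col] = y
    df = pd.DataFrame(data, index=pd.Index(design.run_ids, name="run_id"))
    return ResponseTable(df, scaled=True)


# ---------------------------------------------------------------------------
# Solvent screening
# ---------------------------------------------------------------------------

#: baseline EE abundance per subclass (arbitrary area units, spanning the
#: orders of magnitude typical of subclass sums)
_SCREEN_BASE = {
    "TG": 5.2e8, "TG_1OX": 1.8e6, "TG_2OX": 9.5e5, "DG": 2.4e7, "DG_OX": 3.1e5,
    "ChE": 6.0e5, "BisMePA": 2.2e5, "LPC": 3.5e6, "PC": 1.6e7, "PE": 8.4e6,
    "LPE": 1.1e6, "PI": 4.7e6, "LPI": 2.9e5, "PS": 1.9e6, "LPS": 1.5e5,
    "SM": 7.8e6, "Cer": 2.6e6, "Hex1Cer": 1.3e6,
}

# per-subclass relative ME-vs-EE mean shift (all below the 20% bound) and
# IE displacement magnitude; IE is pushed to the opposite side of EE so the
# group means order ME .. EE .. IE per subclass
_ME_REL = (0.10, -0.07, 0.05, -0.10, 0.08, 0.06, -0.05, 0.07, -0.09, 0.06,
           0.10, -0.06, 0.08, -0.10, 0.05, 0.09, -0.07, 0.08)
_IE_MAG = (0.30, 0.25, 0.35, 0.28, 0.32, 0.26, 0.34, 0.30, 0.27, 0.33,
           0.29, 0.31, 0.25, 0.35, 0.28, 0.30, 0.26, 0.32)


def screening_group_means() -> pd.DataFrame:
    """True group means per solvent × subclass used by the generator."""
    rows = {}
    for j, col in enumerate(RESPONSE_COLUMNS):
        mu = _SCREEN_BASE[col]
        me = mu * (1.0 + _ME_REL[j])
        ie = mu * (1.0 - np.sign(_ME_REL[j]) * _IE_MAG[j])
        rows[col] = {"ME": me, "EE": mu, "IE": ie}
    return pd.DataFrame(rows).T  # subclass × solvent


def gen_solvent_screening(config: GeneratorConfig = GeneratorConfig()) -> pd.DataFrame:
    """Labeled screening table: sample_id, solvent, 18 subclass columns.

    ME and IE means are displaced to opposite sides of EE (|ME−EE|/EE < 0.20
    per subclass by construction; |IE−EE|/EE 0.25-0.35), with Gaussian
    within-group noise of CV ``within_group_cv``.  ME vs IE are therefore
    clearly separable while EE overlaps both — the qualitative structure the
    screening diagnostics are meant to detect.
    """
    rng = np.random.default_rng(config.seed)
    means = screening_group_means()
    n = config.n_per_solvent
    rows = []
    ids = []
    solvents = []
    for solvent in ("ME", "EE", "IE"):
        mu = means[solvent].to_numpy()
        cv = config.within_group_cv * (config.ee_cv_multiplier if solvent == "EE" else 1.0)
        noise = rng.normal(0.0, 1.0, size=(n, len(mu)))
        block = mu * (1.0 + cv * noise)
        rows.append(block)
        ids += [f"{solvent}{i + 1:02d}" for i in range(n)]
        solvents += [solvent] * n
    df = pd.DataFrame(np.vstack(rows), columns=list(RESPONSE_COLUMNS))
    df.insert(0, "solvent", solvents)
    df.insert(0, "sample_id", ids)
    return df


# ---------------------------------------------------------------------------
# Lipid identification fixture (deterministic, no randomness)
# ---------------------------------------------------------------------------


def _pair_unique(pools: list[list[tuple[str, int]]]) -> list[tuple[str, ...]]:
    """Arrange per-position FA multisets into unique chain tuples.

    ``pools`` gives (token, multiplicity) pairs per sn position; the result
    realizes every multiset exactly while all tuples are distinct.  Rows are
    laid out greedily: first-position tokens in decreasing multiplicity, and
    within each block the most-abundant remaining tokens of the later
    positions that keep the tuple unseen — balancing depletion so rare
    tokens stay available where uniqueness gets tight.  Deterministic.
    """
    from collections import Counter

    counters = [Counter(dict(p)) for p in pools]
    n = sum(counters[0].values())

    def candidates(counter: Counter) -> list[str]:
        return sorted((t for t, c in counter.items() if c > 0), key=lambda t: (-counter[t], t))

    out: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for a in sorted(counters[0], key=lambda t: (-counters[0][t], t)):
        for _ in range(counters[0][a]):
            if len(counters) == 2:
                picks = [
                    (b,) for b in candidates(counters[1]) if (a, b) not in seen
                ][:1]
            else:
                picks = [
                    (b, c)
                    for b in candidates(counters[1])
                    for c in candidates(counters[2])
                    if (a, b, c) not in seen
                ][:1]
            if not picks:
                raise RuntimeError("per-position FA multisets cannot form unique tuples")
            rest = picks[0]
            for counter, token in zip(counters[1:], rest):
                counter[token] -= 1
            row = (a, *rest)
            seen.add(row)
            out.append(row)
    assert len(out) == n and len(seen) == n
    return out

# per-position FA multisets realizing the published TG tallies:
#   sn-1: 274 SFA / 48 MUFA / 0 PUFA;  46% S-C, 10% M-C, 44% L-C
#   sn-2: 205 SFA / 101 MUFA / 16 PUFA; 34% S-C, 20% M-C, 46% L-C; 18:1 in 60
#   sn-3: ~equal SFA/MUFA/PUFA; 5% S-C, 15% M-C, 80% L-C
_TG_SN1 = [("4:0", 87), ("6:0", 21), ("8:0", 20), ("10:0", 20),
           ("12:0", 10), ("14:0", 12), ("15:0", 10),
           ("16:0", 60), ("17:0", 14), ("18:0", 20), ("18:1", 48)]
_TG_SN2 = [("4:0", 40), ("6:0", 35), ("8:0", 35), ("12:0", 20), ("14:0", 30),
           ("15:0", 14), ("16:0", 21), ("18:0", 10),
           ("18:1", 60), ("16:1", 41), ("18:2", 14), ("18:3", 2)]
_TG_SN3 = [("4:0", 16), ("14:0", 30), ("15:0", 18), ("16:0", 25), ("17:0", 8),
           ("18:0", 10), ("18:1", 107),
           ("18:2", 50), ("18:3", 30), ("20:4", 10), ("20:5", 9), ("22:5", 9)]

# DG: sn-1 87% SFA / 13% MUFA / 0 PUFA with the TG sn-1 chain-length trend;
#     sn-2 17 SFA / 10 MUFA / 12 PUFA, L-C 64% / M-C 28% / S-C 8%
_DG_SN1 = [("4:0", 7), ("6:0", 5), ("8:0", 5), ("14:0", 4),
           ("16:0", 7), ("18:0", 6), ("18:1", 5)]
_DG_SN2 = [("4:0", 3), ("14:0", 6), ("15:0", 2), ("16:0", 6),
           ("18:1", 7), ("14:1", 3), ("18:2", 6), ("18:3", 6)]


def _grade(i: int) -> str:
    return "ABCD"[(i * 7) % 4]


def _area(i: int) -> float:
    return round(1.0e5 * (1 + (i * 37) % 97) / (1 + (i % 7)), 1)


def gen_lipid_fixture() -> pd.DataFrame:
    """Deterministic identification table reproducing the reported inventory.

    449 species over 18 subclass groups: 322 TG (+NH4/+Na), 13 TG_1OX (nine
    with 18:1+O, four with 18:2+O) and 11 TG_2OX (18:2+OO), 39 DG and one
    DG_OX, 8 LPC, 3 positive-mode and 6 negative-mode PC, 8 PE, 1 BisMePA,
    1 ChE in positive mode; 6 Cer, 4 Hex1Cer, 3 Hex2Cer, 8 SM (+HCOO), 5 PI,
    3 PS, 4 LPE, 2 LPS, 1 LPI (−H) in negative mode.  Six oxidized species
    share their chain composition with a non-oxidized parent.  Columns:
    LipidName, Adduct, IonMode, Grade, Area.
    """
    rows: list[tuple[str, str, str]] = []  # (name, adduct, ion_mode)

    tg = _pair_unique([_TG_SN1, _TG_SN2, _TG_SN3])
    for i, (a, b, c) in enumerate(tg):
        adduct = "+Na" if i % 5 == 4 else "+NH4"
        rows.append((f"TG({a}/{b}/{c})", adduct, "positive"))

    # oxidized TG: six of the oxidized species (4 + 1 + 1) keep the chain
    # composition of an existing parent TG
    ox_names: list[str] = []
    parents_181 = [t for t in tg if t[1] == "18:1"][:4]
    for a, b, c in parents_181:
        ox_names.append(f"TG({a}/{b}+O/{c})")
    # the remaining oxidized species carry an 11:0 chain absent from the TG
    # pools, so exactly the six species above/below have a detected parent
    ox_names += [
        "TG(11:0/18:1+O/20:4)", "TG(11:0/18:1+O/20:5)", "TG(11:0/18:1+O/22:5)",
        "TG(11:0/18:1+O/18:2)", "TG(11:0/18:1+O/18:3)",
    ]
    parent_182 = [t for t in tg if t[2] == "18:2"][0]
    ox_names.append(f"TG({parent_182[0]}/{parent_182[1]}/{parent_182[2]}+O)")
    ox_names += ["TG(11:0/16:0/18:2+O)", "TG(11:0/14:0/18:2+O)", "TG(11:0/18:0/18:2+O)"]
    assert len(ox_names) == 13  # TG_1OX
    parent_2ox = [t for t in tg if t[2] == "18:2"][1]
    ox2_names = [f"TG({parent_2ox[0]}/{parent_2ox[1]}/{parent_2ox[2]}+OO)"]
    ox2_names += [
        "TG(11:0/4:0/18:2+OO)", "TG(11:0/6:0/18:2+OO)", "TG(11:0/8:0/18:2+OO)",
        "TG(11:0/12:0/18:2+OO)", "TG(11:0/14:0/18:2+OO)", "TG(11:0/15:0/18:2+OO)",
        "TG(11:0/16:0/18:2+OO)", "TG(11:0/18:0/18:2+OO)", "TG(11:0/18:1/18:2+OO)",
        "TG(11:0/16:1/18:2+OO)",
    ]
    assert len(ox2_names) == 11  # TG_2OX
    for i, name in enumerate(ox_names + ox2_names):
        rows.append((name, ("+NH4", "+Na", "+H")[i % 3], "positive"))

    dg = _pair_unique([_DG_SN1, _DG_SN2])
    for a, b in dg:
        rows.append((f"DG({a}/{b})", "+NH4", "positive"))
    rows.append(("DG(17:0/18:2+OO)", "+NH4", "positive"))  # DG_OX, no parent

    for fa in ("12:0", "14:0", "15:0", "16:0", "17:0", "18:0", "18:1", "18:2"):
        rows.append((f"LPC({fa})", "+H", "positive"))
    for name in ("PC(16:0/18:1)", "PC(16:0/18:2)", "PC(18:0/18:1)"):
        rows.append((name, "+H", "positive"))
    for name in (
        "PE(16:0/18:1)", "PE(16:0/18:2)", "PE(18:0/18:1)", "PE(18:0/18:2)",
        "PE(18:1/18:1)", "PE(18:1/18:2)", "PE(17:0/18:1)", "PE(15:0/18:2)",
    ):
        rows.append((name, "+H", "positive"))
    rows.append(("BisMePA(16:0/18:1)", "+Na", "positive"))
    rows.append(("ChE(18:1)", "+H-H2O", "positive"))

    for name in (
        "Cer(d18:1/16:0)", "Cer(d18:1/22:0)", "Cer(d18:1/23:0)",
        "Cer(d18:1/24:0)", "Cer(d16:1/22:0)", "Cer(d16:1/24:0)",
    ):
        rows.append((name, "+HCOO", "negative"))
    for name in (
        "Hex1Cer(d18:1/16:0)", "Hex1Cer(d18:1/22:0)",
        "Hex1Cer(d18:1/24:0)", "Hex1Cer(d16:1/23:0)",
    ):
        rows.append((name, "+HCOO", "negative"))
    for name in ("Hex2Cer(d18:1/16:0)", "Hex2Cer(d18:1/22:0)", "Hex2Cer(d18:1/24:0)"):
        rows.append((name, "+HCOO", "negative"))
    for name in (
        "PC(16:0/18:1)", "PC(14:0/18:1)", "PC(15:0/18:2)",
        "PC(17:0/18:1)", "PC(18:1/18:2)", "PC(18:0/18:2)",
    ):
        rows.append((name, "+HCOO", "negative"))
    # SM totals span 32:1-42:1 with one 39:0
    for name in (
        "SM(d16:1/16:0)", "SM(d18:1/16:0)", "SM(d18:1/18:0)", "SM(d18:1/20:0)",
        "SM(d18:0/21:0)", "SM(d18:1/22:0)", "SM(d18:1/23:0)", "SM(d18:1/24:0)",
    ):
        rows.append((name, "+HCOO", "negative"))
    for name in (
        "PI(16:0/18:1)", "PI(16:0/18:2)", "PI(18:0/18:1)",
        "PI(18:0/18:2)", "PI(18:1/18:2)",
    ):
        rows.append((name, "-H", "negative"))
    for name in ("PS(16:0/18:1)", "PS(18:0/18:1)", "PS(18:0/18:2)"):
        rows.append((name, "-H", "negative"))
    for fa in ("16:0", "18:0", "18:1", "18:2"):
        rows.append((f"LPE({fa})", "-H", "negative"))
    rows.append(("LPS(16:0)", "-H", "negative"))
    rows.append(("LPS(18:1)", "-H", "negative"))
    rows.append(("LPI(18:0)", "-H", "negative"))

    oxidized = {i for i, (name, _, _) in enumerate(rows) if "+O" in name.split("(", 1)[1]}
    records = []
    for i, (name, adduct, mode) in enumerate(rows):
        grade = "AB"[i % 2] if i in oxidized else _grade(i)
        records.append(
            {"LipidName": name, "Adduct": adduct, "IonMode": mode,
             "Grade": grade, "Area": _area(i)}
        )
    return pd.DataFrame(records)


def gen_method_comparison_pair() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Illustrative (MAE, Folch) identification-table pair.

    The Folch variant gains TG, phospholipid and sphingolipid species and
    loses part of the oxidized TG, DG, LPC and LPE sets — the qualitative
    direction reported for the classic extraction.
    """
    mae = gen_lipid_fixture()
    folch = mae.copy()
    drop_mask = (
        folch["LipidName"].str.contains(r"\+OO?\)", regex=True)
        & folch["LipidName"].str.startswith("TG")
    )
    drop_idx = list(folch.index[drop_mask][:8])
    drop_idx += list(folch.index[folch["LipidName"].str.startswith("DG(")][:6])
    drop_idx += list(folch.index[folch["LipidName"].str.startswith("LPC(")][:3])
    drop_idx += list(folch.index[folch["LipidName"].str.startswith("LPE(")][:2])
    folch = folch.drop(index=drop_idx)
    extra = [
        ("TG(19:0/18:1/18:2)", "+NH4", "positive"), ("TG(21:0/18:1/18:2)", "+NH4", "positive"),
        ("TG(19:0/16:1/18:3)", "+Na", "positive"), ("TG(21:0/16:1/18:3)", "+NH4", "positive"),
        ("PE(19:0/18:1)", "+H", "positive"), ("PC(19:0/18:1)", "+H", "positive"),
        ("SM(d18:1/25:0)", "+HCOO", "negative"), ("Cer(d18:1/25:0)", "+HCOO", "negative"),
        ("Hex1Cer(d18:1/25:0)", "+HCOO", "negative"), ("PI(17:0/18:1)", "-H", "negative"),
        ("PS(17:0/18:1)", "-H", "negative"),
    ]
    add = pd.DataFrame(
        [
            {"LipidName": n, "Adduct": a, "IonMode": m, "Grade": "B", "Area": _area(900 + i)}
            for i, (n, a, m) in enumerate(extra)
        ]
    )
    folch = pd.concat([folch, add], ignore_index=True)
    return mae, folch


# ---------------------------------------------------------------------------
# QC replicates
# ---------------------------------------------------------------------------

#: deuterated internal standards injected with every QC mix
QC_STANDARDS = (
    "PC(15:0/18:1)-d7", "PE(15:0/18:1)-d7", "PS(15:0/18:1)-d7",
    "PI(15:0/18:1)-d7", "LPC(18:1)-d7", "LPE(18:1)-d7",
    "SM(d18:1/18:1)-d9", "Cer(d18:1/15:0)-d7", "TG(15:0/18:1/15:0)-d7",
    "DG(15:0/18:1)-d7", "ChE(18:1)-d7", "TG(9:0/9:0/9:0)",
)


def gen_qc_table(
    config: GeneratorConfig = GeneratorConfig(),
    true_rsd_pct: dict[str, float] | float = 5.0,
    n_replicates: int = 6,
) -> dict[str, np.ndarray]:
    """Replicate peak areas per deuterated standard at a configured true RSD."""
    rng = np.random.default_rng(config.seed)
    if not isinstance(true_rsd_pct, dict):
        true_rsd_pct = {std: float(true_rsd_pct) for std in QC_STANDARDS}
    out = {}
    for i, (std, rsd) in enumerate(true_rsd_pct.items()):
        mean = 1.0e6 * (1 + i % 5)
        out[std] = rng.normal(mean, mean * rsd / 100.0, size=n_replicates)
    return out
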