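"""Lipid shorthand parsing, fatty-acyl characterization and inventory reports.

Identification software exports lipids in shorthand such as
``TG(4:0/18:1/18:2)`` or ``Cer(d18:1/16:0)``: a class token followed by
chains of the form ``[d]C:D[+O|+OO]`` where C is the carbon count, D the
double-bond count, a ``d`` prefix marks a sphingoid (dihydroxy) base, and
``+O``/``+OO`` one or two added oxygens on an oxidized chain.  ``/``
separates chains whose sn position on the glycerol backbone is resolved
(sn-1/sn-2/sn-3 in written order); ``_`` marks an unresolved chain order.
Oxidation promotes the subclass: TG with one added oxygen → TG_1OX, with
two → TG_2OX; DG with any → DG_OX.

Fatty acyls are characterized on two taxonomies:

* saturation — SFA (0 double bonds), MUFA (1), PUFA (≥2);
* chain length — short (S-C, 4–10 carbons), medium (M-C, 11–15), long
  (L-C, ≥16 by default; the boundary is configurable because usage in the
  field wobbles between ">16" and "≥16", and only ≥16 makes the three
  classes a partition).

Diacylglycerol positional isomers sn-1,2 and sn-2,3 are indistinguishable
in untargeted work; DG positions are labelled sn-1/sn-2 purely by
convention.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FattyAcyl",
    "LipidSpecies",
    "FAAnnotation",
    "SubclassSummary",
    "QCReport",
    "LipidParseError",
    "UnknownLipidClassError",
    "ChainCountError",
    "MalformedChainError",
    "parse_lipid_name",
    "classify_fa",
    "summarize_inventory",
    "compare_methods",
    "qc_check",
    "read_identification_table",
    "SUBCLASS_GROUPS_18",
]

# chains expected per base class token
CHAIN_COUNTS = {
    "TG": 3, "DG": 2, "ChE": 1, "BisMePA": 2,
    "LPC": 1, "PC": 2, "PE": 2, "LPE": 1,
    "PI": 2, "LPI": 1, "PS": 2, "LPS": 1,
    "SM": 2, "Cer": 2, "Hex1Cer": 2, "Hex2Cer": 2,
}

# fine subclass -> 18-group label (hexosylceramides report as one group)
SUBCLASS_GROUPS_18 = {
    "Hex1Cer": "HexCer",
    "Hex2Cer": "HexCer",
}

_NEGATIVE_ADDUCTS = {"-H", "+HCOO"}

_CHAIN_RE = re.compile(r"^(d?)(\d+):(\d+)(\+OO|\+O)?$")
_NAME_RE = re.compile(r"^([A-Za-z0-9]+)\((.+)\)$")


class LipidParseError(ValueError):
    """Base class for shorthand parsing failures."""


class UnknownLipidClassError(LipidParseError):
    pass


class ChainCountError(LipidParseError):
    pass


class MalformedChainError(LipidParseError):
    pass


@dataclass(frozen=True)
class FattyAcyl:
    carbons: int
    double_bonds: int
    oxygens_added: int = 0
    sphingoid: bool = False
    sn_index: int | None = None

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"fatty acyl needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds * 2 > self.carbons:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} is impossible (too many double bonds)"
            )
        if self.oxygens_added not in (0, 1, 2):
            raise ValueError("oxygens_added must be 0, 1 or 2")

    @property
    def token(self) -> str:
        s = f"{'d' if self.sphingoid else ''}{self.carbons}:{self.double_bonds}"
        return s + ("+OO" if self.oxygens_added == 2 else "+O" if self.oxygens_added == 1 else "")

    def deoxidized(self) -> "FattyAcyl":
        return replace(self, oxygens_added=0)


@dataclass(frozen=True)
class FAAnnotation:
    saturation: str  # SFA | MUFA | PUFA
    chain_length_class: str  # S-C | M-C | L-C
    odd_chain: bool


def classify_fa(chain: FattyAcyl, long_chain_min: int = 16) -> FAAnnotation:
    """Total classification of a fatty acyl on saturation and chain length."""
    sat = "SFA" if chain.double_bonds == 0 else "MUFA" if chain.double_bonds == 1 else "PUFA"
    if chain.carbons >= long_chain_min:
        length = "L-C"
    elif chain.carbons >= 11:
        length = "M-C"
    else:
        length = "S-C"
    return FAAnnotation(saturation=sat, chain_length_class=length, odd_chain=chain.carbons % 2 == 1)


@dataclass(frozen=True)
class LipidSpecies:
    subclass: str
    chains: tuple[FattyAcyl, ...]
    sn_resolved: bool
    adduct: str = ""
    ion_mode: str = ""
    grade: str = ""
    raw_name: str = ""

    def __post_init__(self) -> None:
        if self.ion_mode and self.adduct:
            neg = self.adduct in _NEGATIVE_ADDUCTS
            if (self.ion_mode == "negative") != neg:
                raise ValueError(
                    f"ion mode {self.ion_mode!r} inconsistent with adduct {self.adduct!r}"
                )

    @property
    def base_class(self) -> str:
        return {"TG_1OX": "TG", "TG_2OX": "TG", "DG_OX": "DG"}.get(self.subclass, self.subclass)

    @property
    def total_oxygens_added(self) -> int:
        return sum(c.oxygens_added for c in self.chains)

    @property
    def canonical_name(self) -> str:
        sep = "/" if self.sn_resolved else "_"
        return f"{self.base_class}({sep.join(c.token for c in self.chains)})"

    @property
    def key(self) -> tuple[str, str]:
        """Species identity: canonical name keyed by ion mode."""
        return (self.canonical_name, self.ion_mode)

    def composition_key(self) -> tuple:
        """Chain composition ignoring added oxygens; unordered when sn is unresolved."""
        toks = [c.deoxidized().token for c in self.chains]
        return (self.base_class, tuple(toks) if self.sn_resolved else tuple(sorted(toks)))


def _parse_chain(token: str, index: int | None) -> FattyAcyl:
    m = _CHAIN_RE.match(token)
    if not m:
        raise MalformedChainError(f"malformed chain token {token!r}")
    d, c, db, ox = m.groups()
    try:
        return FattyAcyl(
            carbons=int(c),
            double_bonds=int(db),
            oxygens_added=0 if not ox else (1 if ox == "+O" else 2),
            sphingoid=bool(d),
            sn_index=index,
        )
    except ValueError as e:
        raise MalformedChainError(f"chain token {token!r}: {e}") from e


def parse_lipid_name(name: str, adduct: str = "", ion_mode: str = "", grade: str = "") -> LipidSpecies:
    """Parse a shorthand lipid name into a structured species.

    Raises :class:`UnknownLipidClassError`, :class:`ChainCountError` or
    :class:`MalformedChainError` with the offending token.
    """
    if not name or not name.strip():
        raise LipidParseError("empty lipid name")
    m = _NAME_RE.match(name.strip())
    if not m:
        raise LipidParseError(f"cannot parse lipid name {name!r}")
    cls, chainstr = m.groups()
    if cls not in CHAIN_COUNTS:
        raise UnknownLipidClassError(f"unknown lipid class token {cls!r} in {name!r}")
    if "/" in chainstr and "_" in chainstr:
        raise MalformedChainError(f"mixed '/' and '_' separators in {name!r}")
    resolved = "_" not in chainstr
    tokens = chainstr.split("/" if resolved else "_")
    if len(tokens) != CHAIN_COUNTS[cls]:
        raise ChainCountError(
            f"{cls} expects {CHAIN_COUNTS[cls]} chains, got {len(tokens)} in {name!r}"
        )
    chains = tuple(
        _parse_chain(tok, i + 1 if resolved else None) for i, tok in enumerate(tokens)
    )
    total_ox = sum(c.oxygens_added for c in chains)
    subclass = cls
    if cls == "TG" and total_ox:
        subclass = "TG_1OX" if total_ox == 1 else "TG_2OX"
    elif cls == "DG" and total_ox:
        subclass = "DG_OX"
    return LipidSpecies(
        subclass=subclass,
        chains=chains,
        sn_resolved=resolved,
        adduct=adduct,
        ion_mode=ion_mode,
        grade=grade,
        raw_name=name.strip(),
    )


def read_identification_table(source, max_unparseable: float = 1.0) -> list[LipidSpecies]:
    """Parse a delimited identification export (or DataFrame).

    Expects columns LipidName, Adduct, IonMode, Grade (Area and extras are
    ignored here).  If the fraction of unparseable rows exceeds
    ``max_unparseable``, raises with a line-numbered listing.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    species: list[LipidSpecies] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            species.append(
                parse_lipid_name(
                    str(row["LipidName"]),
                    adduct=str(row.get("Adduct", "")),
                    ion_mode=str(row.get("IonMode", "")),
                    grade=str(row.get("Grade", "")),
                )
            )
        except (LipidParseError, ValueError) as e:
            errors.append(f"row {i}: {e}")
    if len(df) and len(errors) / len(df) > max_unparseable:
        raise LipidParseError(
            f"{len(errors)}/{len(df)} rows unparseable:\n" + "\n".join(errors)
        )
    return species


# ---------------------------------------------------------------------------
# Inventory summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubclassSummary:
    """Descriptive statistics of a parsed lipid inventory."""

    counts: dict  # fine subclass -> species count
    n_species: int
    n_subclasses: int  # 18-group count (HexCer grouped)
    positional: dict  # family -> sn position -> {"saturation": Counter, "chain_length": Counter, "top_fa": [(token, n), ...]}
    oxidized_links: tuple  # (oxidized canonical name, parent canonical name)

    def grouped_counts(self) -> dict:
        out: Counter = Counter()
        for sub, n in self.counts.items():
            out[SUBCLASS_GROUPS_18.get(sub, sub)] += n
        return dict(out)

    def positional_percentages(self, family: str, position: int, taxonomy: str) -> dict:
        tally = self.positional[family][position][taxonomy]
        total = sum(tally.values())
        return {k: 100.0 * v / total for k, v in tally.items()} if total else {}


def _positional_tallies(species: list[LipidSpecies], base_class: str) -> dict:
    members = [s for s in species if s.subclass == base_class]
    if not members:
        return {}
    n_pos = CHAIN_COUNTS[base_class]
    out = {}
    for pos in range(1, n_pos + 1):
        sat: Counter = Counter()
        length: Counter = Counter()
        fa: Counter = Counter()
        for s in members:
            chain = s.chains[pos - 1]
            ann = classify_fa(chain)
            sat[ann.saturation] += 1
            length[ann.chain_length_class] += 1
            fa[chain.token] += 1
        out[pos] = {
            "saturation": sat,
            "chain_length": length,
            "top_fa": fa.most_common(3),
        }
    return out


def _oxidized_links(species: list[LipidSpecies]) -> tuple:
    """Match oxidized species to a non-oxidized parent with identical chains.

    Comparison ignores added oxygens; chain order is ignored whenever either
    side has unresolved sn positions.
    """
    plain = {}
    for s in species:
        if s.total_oxygens_added == 0:
            plain.setdefault((s.base_class, tuple(sorted(c.token for c in s.chains))), s)
    links = []
    for s in species:
        if s.total_oxygens_added == 0:
            continue
        key = (s.base_class, tuple(sorted(c.deoxidized().token for c in s.chains)))
        parent = plain.get(key)
        if parent is not None:
            links.append((s.canonical_name, parent.canonical_name))
    return tuple(links)


def summarize_inventory(species) -> SubclassSummary:
    """Counts, per-position composition tallies and oxidized↔parent links."""
    species = list(species)
    counts = Counter(s.subclass for s in species)
    grouped = {SUBCLASS_GROUPS_18.get(sub, sub) for sub in counts}
    positional = {}
    for fam in ("TG", "DG"):
        t = _positional_tallies(species, fam)
        if t:
            positional[fam] = t
    return SubclassSummary(
        counts=dict(counts),
        n_species=len(species),
        n_subclasses=len(grouped),
        positional=positional,
        oxidized_links=_oxidized_links(species),
    )


def compare_methods(table_a, table_b, names=("A", "B")) -> pd.DataFrame:
    """Per-subclass species-set comparison of two inventories.

    Species identity is the canonical name keyed by ion mode.  Returns one
    row per subclass present in either inventory with counts, shared and
    unique species numbers; the unique species themselves are attached in
    ``DataFrame.attrs['unique']``.
    """
    a = {s.key: s for s in table_a}
    b = {s.key: s for s in table_b}
    subclasses = sorted({s.subclass for s in list(a.values()) + list(b.values())})
    rows = []
    unique: dict = {}
    for sub in subclasses:
        ka = {k for k, s in a.items() if s.subclass == sub}
        kb = {k for k, s in b.items() if s.subclass == sub}
        rows.append(
            {
                "subclass": sub,
                f"count_{names[0]}": len(ka),
                f"count_{names[1]}": len(kb),
                "shared": len(ka & kb),
                f"only_{names[0]}": len(ka - kb),
                f"only_{names[1]}": len(kb - ka),
            }
        )
        unique[sub] = {names[0]: sorted(k[0] for k in ka - kb), names[1]: sorted(k[0] for k in kb - ka)}
    df = pd.DataFrame(rows)
    df.attrs["unique"] = unique
    return df


# ---------------------------------------------------------------------------
# QC gate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCReport:
    """Relative standard deviation gate over replicate standard injections."""

    table: pd.DataFrame  # index: standard; columns: mean, sd, rsd_pct, passed, note
    threshold_pct: float

    @property
    def all_passed(self) -> bool:
        return bool(self.table["passed"].all())


def qc_check(areas, threshold_pct: float = 20.0) -> QCReport:
    """RSD% gate per standard: pass iff 100·sd/mean < threshold (strict).

    ``areas`` maps standard name -> replicate peak areas (>= 2 each).
    A zero mean makes RSD undefined: the standard fails with a reason.
    """
    rows = {}
    for std, vals in areas.items():
        x = np.asarray(list(vals), float)
        if x.size < 2:
            raise ValueError(f"standard {std!r}: need >= 2 replicates")
        mean = x.mean()
        sd = x.std(ddof=1)
        if mean == 0:
            rows[std] = [0.0, sd, np.nan, False, "undefined RSD (zero mean)"]
            continue
        rsd = 100.0 * sd / abs(mean)
        rows[std] = [mean, sd, rsd, bool(rsd < threshold_pct), ""]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean", "sd", "rsd_pct", "passed", "note"]
    )
    return QCReport(table=table, threshold_pct=threshold_pct)
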