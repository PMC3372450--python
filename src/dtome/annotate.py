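"""ATC drug classification and hypergeometric gene-set enrichment.

The WHO Anatomical Therapeutic Chemical (ATC) system classifies active
drugs at five nested levels: an anatomical main-group letter (14 groups,
e.g. N = nervous system), a two-digit therapeutic subgroup, a one-letter
therapeutic/pharmacological subgroup (e.g. N05A antipsychotics), a
one-letter chemical subgroup, and a two-digit substance code.

Over-representation of a query gene set in a collection (GMT format) is
scored with the upper-tail hypergeometric test

    P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the background size, K the set size, n the query size and k the
overlap, followed by Benjamini-Hochberg step-up adjustment across tested
sets. Sets with zero overlap are excluded from the adjustment by default
(they cannot be significant and only inflate the number of tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import InputError, ValidationError
from .netbuild import DRUG_ROLES, DTomeNetwork

logger = logging.getLogger(__name__)

ATC_LEVEL1_LETTERS = frozenset("ABCDGHJLMNPRSV")

_LEVEL_LENGTHS = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}
_VALID_LENGTHS = frozenset(_LEVEL_LENGTHS.values())


# ---------------------------------------------------------------------------
# ATC codes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ATCCode:
    raw: str
    level1: str
    level2: str | None = None
    level3: str | None = None
    level4: str | None = None
    level5: str | None = None

    @property
    def depth(self) -> int:
        for lvl in (5, 4, 3, 2, 1):
            if getattr(self, f"level{lvl}") is not None:
                return lvl
        raise AssertionError("unreachable: level1 is mandatory")

    def prefix(self, level: int) -> str | None:
        """The code truncated to ``level``; None if the code is shallower."""
        if level not in _LEVEL_LENGTHS:
            raise ValidationError(f"ATC level must be 1-5, got {level}")
        return getattr(self, f"level{level}")


def parse_atc(raw: str) -> ATCCode:
    """Parse an ATC code of depth 1-5, validating the positional grammar."""
    code = (raw or "").strip().upper()
    if len(code) not in _VALID_LENGTHS:
        raise ValidationError(
            f"ATC code {raw!r} has invalid length {len(code)}; valid lengths are 1,3,4,5,7"
        )
    checks = [
        (0, lambda c: c in ATC_LEVEL1_LETTERS, "anatomical main-group letter"),
        (1, str.isdigit, "digit"),
        (2, str.isdigit, "digit"),
        (3, str.isalpha, "letter"),
        (4, str.isalpha, "letter"),
        (5, str.isdigit, "digit"),
        (6, str.isdigit, "digit"),
    ]
    for pos, ok, what in checks[: len(code)]:
        if not ok(code[pos]):
            raise ValidationError(
                f"ATC code {raw!r}: position {pos + 1} must be a {what}, got {code[pos]!r}"
            )
    return ATCCode(
        raw=code,
        level1=code[:1],
        level2=code[:3] if len(code) >= 3 else None,
        level3=code[:4] if len(code) >= 4 else None,
        level4=code[:5] if len(code) >= 5 else None,
        level5=code[:7] if len(code) >= 7 else None,
    )


def format_atc(code: ATCCode) -> str:
    """The textual form of a parsed code (inverse of :func:`parse_atc`)."""
    return code.prefix(code.depth)


@dataclass
class AtcGrouping:
    level: int
    groups: pd.DataFrame  # columns: group, members, count, fraction
    n_classified: int
    unclassified: list[str]


def group_drugs_by_atc(drug_codes, level: int) -> AtcGrouping:
    """Group drugs by their ATC prefix at the chosen level.

    ``drug_codes`` is an iterable of (drug_id, list-of-code-strings). A drug
    with several codes contributes once to each distinct group; drugs
    without any code are reported as unclassified. Fractions are relative
    to the number of classified drugs (>= 1 code), so with multi-coded
    drugs they may sum above 1.
    """
    if level not in _LEVEL_LENGTHS:
        raise ValidationError(f"ATC level must be 1-5, got {level}")
    members: dict[str, set[str]] = {}
    classified: set[str] = set()
    unclassified: list[str] = []
    for drug_id, codes in drug_codes:
        codes = [c for c in codes if c and c.strip()]
        if not codes:
            unclassified.append(drug_id)
            continue
        classified.add(drug_id)
        prefixes = set()
        for c in codes:
            prefix = parse_atc(c).prefix(level)
            if prefix is not None:
                prefixes.add(prefix)
        for p in prefixes:
            members.setdefault(p, set()).add(drug_id)
    n_classified = len(classified)
    rows = [
        {
            "group": g,
            "members": sorted(ids),
            "count": len(ids),
            "fraction": len(ids) / n_classified if n_classified else 0.0,
        }
        for g, ids in members.items()
    ]
    table = pd.DataFrame(rows, columns=["group", "members", "count", "fraction"])
    if not table.empty:
        table = table.sort_values(
            ["count", "group"], ascending=[False, True], ignore_index=True
        )
    return AtcGrouping(
        level=level,
        groups=table,
        n_classified=n_classified,
        unclassified=sorted(unclassified),
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


def parse_gmt(path) -> list[GeneSet]:
    """Read a GMT gene-set collection (name, description, members...)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path} line {ln}: GMT rows need name, description, >=1 gene")
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not members:
                raise InputError(f"{path} line {ln}: gene set {fields[0]!r} has no members")
            sets.append(GeneSet(name=fields[0], description=fields[1], members=members))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def hypergeom_p(k, K, n, N):
    """Upper-tail (over-representation) hypergeometric probability P(X >= k).

    Accepts scalars or equally shaped arrays; returns a float for scalar
    input. Bounds 0 <= K <= N, 0 <= n <= N, 0 <= k <= min(K, n) are enforced.
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    K_arr = np.atleast_1d(np.asarray(K, dtype=np.int64))
    n_arr = np.atleast_1d(np.asarray(n, dtype=np.int64))
    N_arr = np.atleast_1d(np.asarray(N, dtype=np.int64))
    k_arr, K_arr, n_arr, N_arr = np.broadcast_arrays(k_arr, K_arr, n_arr, N_arr)
    bad = (
        (K_arr < 0)
        | (K_arr > N_arr)
        | (n_arr < 0)
        | (n_arr > N_arr)
        | (k_arr < 0)
        | (k_arr > np.minimum(K_arr, n_arr))
    )
    if bad.any():
        i = int(np.argmax(bad))
        raise ValidationError(
            "hypergeometric bounds violated: "
            f"k={int(k_arr.flat[i])}, K={int(K_arr.flat[i])}, "
            f"n={int(n_arr.flat[i])}, N={int(N_arr.flat[i])}"
        )
    p = np.clip(hypergeom.sf(k_arr - 1, N_arr, K_arr, n_arr), 0.0, 1.0)
    if np.isscalar(k) or np.ndim(k) == 0:
        return float(p.reshape(-1)[0])
    return p


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    adjusted_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, with a stable
    ascending sort so ties keep their relative order.
    """
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return []
    if np.any(~np.isfinite(arr)) or np.any((arr < 0) | (arr > 1)):
        raise ValidationError("p-values must be finite and within [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out.tolist()


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool

    def as_dict(self) -> dict:
        return {
            "set_name": self.set_name,
            "k": self.k,
            "K": self.K,
            "n": self.n,
            "N": self.N,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "significant": self.significant,
        }


def enrich(
    query_genes,
    collection,
    background="collection_union",
    alpha: float = 0.01,
    include_empty: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a query in each gene set.

    Genes outside the background are dropped from both the query and the
    sets before counting. Sets with zero overlap are excluded from the BH
    adjustment unless ``include_empty``. Results are sorted by adjusted p,
    then set name.
    """
    collection = list(collection)
    if not collection:
        raise ValidationError("gene-set collection is empty")
    if isinstance(background, str):
        if background != "collection_union":
            raise ValidationError(
                f"background must be a gene set or the token 'collection_union', got {background!r}"
            )
        bg = set().union(*(gs.members for gs in collection))
    else:
        bg = {g.upper() for g in background}
        if not bg:
            raise ValidationError("explicit background gene set is empty")
    query = {g.upper() for g in query_genes} & bg
    if not query:
        logger.warning("query is empty after intersection with the background")
        return []

    N = len(bg)
    n = len(query)
    tested: list[tuple[str, int, int]] = []
    for gs in collection:
        members = gs.members & bg
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        if k == 0 and not include_empty:
            continue
        tested.append((gs.name, k, K))
    if not tested:
        return []
    p_raw = [hypergeom_p(k, K, n, N) for _, k, K in tested]
    p_adj = bh_adjust(p_raw)
    results = [
        EnrichmentResult(
            set_name=name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=pr,
            p_adj=pa,
            significant=pa < alpha,
        )
        for (name, k, K), pr, pa in zip(tested, p_raw, p_adj)
    ]
    return sorted(results, key=lambda r: (r.p_adj, r.set_name))


def classify_network_nodes(
    net: DTomeNetwork,
    module_labels: dict[str, int],
    collection,
    background="collection_union",
    alpha: float = 0.01,
    top: int = 5,
) -> dict[int, list[EnrichmentResult]]:
    """Per-module enrichment over the module's non-drug nodes (top sets only).

    Modules containing no gene/protein node are skipped with a warning.
    """
    roles = net.node_roles
    out: dict[int, list[EnrichmentResult]] = {}
    for label in sorted(set(module_labels.values())):
        genes = {
            node
            for node, lab in module_labels.items()
            if lab == label and node in net and roles.get(node) not in DRUG_ROLES
        }
        if not genes:
            logger.warning("module %s has no gene nodes; skipped", label)
            continue
        results = enrich(genes, collection, background=background, alpha=alpha)
        out[label] = results[:top]
    return out
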