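"""Cis-instrument construction: gene-window selection, LD clumping, proxy
lookup, allele harmonization, confounder blocklisting, and instrument-strength
metrics.

Selection mirrors standard drug-target MR practice: variants associated with
the exposure at genome-wide significance (p < 5e-8) within ±100 kb of a drug
target gene (window inclusive at both edges), greedily thinned to pairwise
r² < 0.1 keeping the most significant; palindromic (A/T, G/C) variants are
excluded unconditionally; instruments missing from an outcome dataset may be
replaced by a proxy in high LD (r² > 0.80, strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .sumstats_io import LDTable

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

GENOME_WIDE_P = 5e-8
WINDOW_BP = 100_000
CLUMP_R2 = 0.1
PROXY_R2 = 0.8

#: harmonization action tags
KEPT_AS_IS = "kept_as_is"
ALLELE_FLIPPED = "allele_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISSING = "dropped_missing"
DROPPED_MISMATCH = "dropped_mismatch"


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T or G/C pairs: strand cannot be resolved from alleles alone."""
    return COMPLEMENT.get(effect_allele.upper()) == other_allele.upper()


class ProxyHit(NamedTuple):
    variant_id: str
    r2: float


@dataclass
class StrengthResult:
    """Per-SNP and aggregate instrument-strength metrics."""

    per_snp_f: pd.Series
    per_snp_pve: pd.Series
    total_pve: float
    mean_f: float
    #: True iff every per-SNP F exceeds the conventional weak-instrument bound of 10
    all_f_above_10: bool


@dataclass
class InstrumentSet:
    """The validated instrument set for one drug class."""

    class_name: str
    records: pd.DataFrame
    strength: StrengthResult | None
    #: per-SNP provenance: "direct" or "proxy(<original>, r2=<r2>)"
    provenance: dict[str, str]


def select_candidates(
    exposure: pd.DataFrame,
    regions: pd.DataFrame,
    target_genes: Sequence[str],
    p_threshold: float = GENOME_WIDE_P,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Exposure records within ``±window_bp`` of a target gene at ``p < p_threshold``.

    Windows are inclusive at both edges.  Target genes missing from the
    region annotation are logged and skipped; zero usable genes yields an
    empty frame with a warning, not an exception.  The returned frame carries
    a ``genes`` column with the tuple of matching gene symbols per record.
    """
    known = regions.set_index("gene_symbol")
    usable = []
    for gene in target_genes:
        if gene in known.index:
            usable.append(gene)
        else:
            logger.warning("target gene %s has no region annotation; skipped", gene)
    if not usable:
        logger.warning("no usable target genes among %s", list(target_genes))
        out = exposure.iloc[0:0].copy()
        out["genes"] = pd.Series(dtype=object)
        return out

    sig = exposure["pval"] < p_threshold
    hits: dict[int, list[str]] = {}
    for gene in usable:
        reg = known.loc[gene]
        in_win = (
            sig
            & (exposure["chrom"].astype(str) == str(reg["chrom"]))
            & (exposure["pos"] >= int(reg["start"]) - window_bp)
            & (exposure["pos"] <= int(reg["end"]) + window_bp)
        )
        for i in np.flatnonzero(in_win.to_numpy()):
            hits.setdefault(int(i), []).append(gene)
    idx = sorted(hits)
    out = exposure.iloc[idx].copy()
    out["genes"] = [tuple(hits[i]) for i in idx]
    return out.reset_index(drop=True)


def select_candidates_by_class(
    exposure: pd.DataFrame,
    regions: pd.DataFrame,
    class_map: Mapping[str, Sequence[str]],
    p_threshold: float = GENOME_WIDE_P,
    window_bp: int = WINDOW_BP,
) -> dict[str, pd.DataFrame]:
    """Candidate records for every drug class in ``class_map``."""
    return {
        name: select_candidates(exposure, regions, genes, p_threshold, window_bp)
        for name, genes in class_map.items()
    }


def clump(
    candidates: pd.DataFrame,
    ld: LDTable,
    r2_threshold: float = CLUMP_R2,
) -> pd.DataFrame:
    """Greedy LD thinning: keep the most significant mutually-unlinked SNPs.

    Sort ascending by p-value (ties broken by lexicographically smaller
    variant_id for determinism); accept a SNP iff its r² with every already
    accepted SNP is below ``r2_threshold``.  Pairs absent from the LD table
    count as unlinked (logged once).  Output is sorted by (chrom, pos).
    """
    if candidates.empty:
        return candidates.copy()
    order = candidates.sort_values(
        ["pval", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    accepted: list[int] = []
    accepted_ids: list[str] = []
    unknown_pairs = 0
    for i, vid in enumerate(order["variant_id"]):
        ok = True
        for aid in accepted_ids:
            r2 = ld.r2(vid, aid)
            if r2 is None:
                unknown_pairs += 1
                r2 = 0.0
            if r2 >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(i)
            accepted_ids.append(vid)
    if unknown_pairs:
        logger.info("clump: %d unknown LD pairs treated as unlinked", unknown_pairs)
    kept = order.iloc[accepted]
    return kept.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def find_proxy(
    variant_id: str,
    available_ids: Sequence[str],
    ld: LDTable,
    r2_min: float = PROXY_R2,
) -> ProxyHit | None:
    """Best available proxy with r² strictly above ``r2_min``, or None.

    Ties in r² break toward the lexicographically smaller variant id.
    """
    available = set(available_ids)
    best: ProxyHit | None = None
    for other, r2 in sorted(ld.neighbors(variant_id).items()):
        if other not in available or r2 <= r2_min:
            continue
        if best is None or r2 > best.r2:
            best = ProxyHit(other, r2)
    return best


@dataclass
class HarmonizationResult:
    """Kept pairs plus the per-input-record action log."""

    pairs: pd.DataFrame
    actions: pd.DataFrame  # columns: variant_id, action, detail


_PAIR_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta_exp",
    "se_exp",
    "pval_exp",
    "n_exp",
    "beta_out",
    "se_out",
    "n_out",
    "provenance",
]


def harmonize(
    exposure_records: pd.DataFrame,
    outcome: pd.DataFrame,
    *,
    ld: LDTable | None = None,
    proxy_policy: str = "drop",
    r2_min: float = PROXY_R2,
    proxy_source: pd.DataFrame | None = None,
) -> HarmonizationResult:
    """Align exposure and outcome effects to a shared effect allele.

    Rules, applied per exposure record:

    * palindromic (A/T, G/C) records are dropped unconditionally;
    * identical alleles (directly or after strand complementing both outcome
      alleles): outcome effect kept as is;
    * swapped alleles (directly or after complementing): outcome beta
      negated, alleles flipped;
    * anything else: dropped as a mismatch;
    * records absent from the outcome: replaced by a proxy instrument
      (``proxy_policy="proxy"``, requires ``ld``; the proxy must itself be
      present in the outcome and in ``proxy_source`` — the exposure table to
      draw proxies from, defaulting to ``exposure_records`` — and
      non-palindromic) or dropped.

    An empty result is a legitimate skip condition for the caller, not an
    error.
    """
    if proxy_policy not in ("drop", "proxy"):
        raise ValueError(f"proxy_policy must be 'drop' or 'proxy', got {proxy_policy!r}")
    out_by_id: dict[str, pd.Series] = {}
    for _, row in outcome.iterrows():
        out_by_id.setdefault(str(row["variant_id"]), row)
    source = proxy_source if proxy_source is not None else exposure_records
    exp_by_id = {str(row["variant_id"]): row for _, row in source.iterrows()}

    actions: list[dict] = []
    kept_rows: list[dict] = []
    used_ids: set[str] = set()

    def _align(exp_row: pd.Series, out_row: pd.Series) -> tuple[str, float] | None:
        """Return (action, aligned beta_out) or None on mismatch."""
        ea_x, oa_x = exp_row["effect_allele"], exp_row["other_allele"]
        ea_y, oa_y = out_row["effect_allele"], out_row["other_allele"]
        beta_y = float(out_row["beta"])
        if (ea_y, oa_y) == (ea_x, oa_x):
            return KEPT_AS_IS, beta_y
        if (ea_y, oa_y) == (oa_x, ea_x):
            return ALLELE_FLIPPED, -beta_y
        cea, coa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
        if (cea, coa) == (ea_x, oa_x):
            return KEPT_AS_IS, beta_y
        if (cea, coa) == (oa_x, ea_x):
            return ALLELE_FLIPPED, -beta_y
        return None

    def _keep(exp_row: pd.Series, out_row: pd.Series, action: str, beta_y: float,
              provenance: str) -> None:
        kept_rows.append(
            {
                "variant_id": str(exp_row["variant_id"]),
                "chrom": str(exp_row["chrom"]),
                "pos": int(exp_row["pos"]),
                "effect_allele": exp_row["effect_allele"],
                "other_allele": exp_row["other_allele"],
                "eaf": exp_row["eaf"],
                "beta_exp": float(exp_row["beta"]),
                "se_exp": float(exp_row["se"]),
                "pval_exp": float(exp_row["pval"]),
                "n_exp": float(exp_row["n"]),
                "beta_out": beta_y,
                "se_out": float(out_row["se"]),
                "n_out": float(out_row["n"]),
                "provenance": provenance,
            }
        )
        used_ids.add(str(exp_row["variant_id"]))

    for _, exp_row in exposure_records.iterrows():
        vid = str(exp_row["variant_id"])
        if is_palindromic(exp_row["effect_allele"], exp_row["other_allele"]):
            actions.append(
                {"variant_id": vid, "action": DROPPED_PALINDROMIC, "detail": ""}
            )
            continue
        out_row = out_by_id.get(vid)
        if out_row is None:
            hit = None
            if proxy_policy == "proxy" and ld is not None:
                candidate_ids = [
                    i for i in out_by_id
                    if i in exp_by_id and i not in used_ids and i != vid
                    and not is_palindromic(
                        exp_by_id[i]["effect_allele"], exp_by_id[i]["other_allele"]
                    )
                ]
                hit = find_proxy(vid, candidate_ids, ld, r2_min=r2_min)
            if hit is None:
                actions.append(
                    {"variant_id": vid, "action": DROPPED_MISSING, "detail": ""}
                )
                continue
            proxy_exp = exp_by_id[hit.variant_id]
            proxy_out = out_by_id[hit.variant_id]
            aligned = _align(proxy_exp, proxy_out)
            if aligned is None:
                actions.append(
                    {"variant_id": vid, "action": DROPPED_MISSING,
                     "detail": f"proxy {hit.variant_id} allele mismatch"}
                )
                continue
            action, beta_y = aligned
            _keep(proxy_exp, proxy_out, action, beta_y,
                  provenance=f"proxy({vid}, r2={hit.r2:g})")
            actions.append(
                {"variant_id": vid, "action": action,
                 "detail": f"replaced by proxy {hit.variant_id} (r2={hit.r2:g})"}
            )
            continue
        aligned = _align(exp_row, out_row)
        if aligned is None:
            actions.append(
                {"variant_id": vid, "action": DROPPED_MISMATCH,
                 "detail": f"{exp_row['effect_allele']}/{exp_row['other_allele']} vs "
                           f"{out_row['effect_allele']}/{out_row['other_allele']}"}
            )
            continue
        action, beta_y = aligned
        _keep(exp_row, out_row, action, beta_y, provenance="direct")
        actions.append({"variant_id": vid, "action": action, "detail": ""})

    pairs = pd.DataFrame(kept_rows, columns=_PAIR_COLUMNS)
    action_df = pd.DataFrame(actions, columns=["variant_id", "action", "detail"])
    return HarmonizationResult(pairs=pairs, actions=action_df)


def instrument_strength(records: pd.DataFrame, n: float | None = None) -> StrengthResult:
    """Per-SNP F-statistics and variance explained (PVE).

    With ``z = beta/se``: ``PVE = z²/(z² + n)`` and ``F = (n - 2)·PVE/(1 -
    PVE)``; both are monotone increasing in |z| at fixed n.  ``n`` defaults
    to each record's own sample size and must exceed 2.
    """
    if n is not None:
        n_arr = np.full(len(records), float(n))
    else:
        n_arr = records["n"].to_numpy(dtype=float)
    if np.any(n_arr <= 2):
        raise ValueError("instrument_strength requires n > 2")
    z2 = (records["beta"].to_numpy(dtype=float) / records["se"].to_numpy(dtype=float)) ** 2
    pve = z2 / (z2 + n_arr)
    f = (n_arr - 2) * pve / (1 - pve)
    ids = records["variant_id"].astype(str)
    per_snp_pve = pd.Series(pve, index=ids, name="pve")
    per_snp_f = pd.Series(f, index=ids, name="f")
    return StrengthResult(
        per_snp_f=per_snp_f,
        per_snp_pve=per_snp_pve,
        total_pve=float(pve.sum()),
        mean_f=float(f.mean()) if len(f) else float("nan"),
        all_f_above_10=bool(len(f) and np.all(f > 10)),
    )


def apply_blocklist(records: pd.DataFrame, blocklist: pd.DataFrame | None) -> pd.DataFrame:
    """Remove variants listed in a confounder blocklist; removals are logged.

    A variant listed under several confounders is removed once, with every
    label logged.
    """
    if blocklist is None or blocklist.empty:
        return records.copy()
    labels = blocklist.groupby("variant_id")["confounder"].apply(
        lambda s: ",".join(sorted(set(s)))
    )
    listed = records["variant_id"].astype(str).isin(labels.index)
    for vid in records.loc[listed, "variant_id"].astype(str):
        logger.info("blocklist: removed %s (%s)", vid, labels[vid])
    return records.loc[~listed].reset_index(drop=True)


def build_instrument_set(
    class_name: str,
    exposure: pd.DataFrame,
    regions: pd.DataFrame,
    target_genes: Sequence[str],
    ld: LDTable,
    *,
    p_threshold: float = GENOME_WIDE_P,
    window_bp: int = WINDOW_BP,
    r2_threshold: float = CLUMP_R2,
) -> InstrumentSet:
    """Select, clump and score the instrument set for one drug class.

    Palindromic variants are removed at selection time (they could never be
    harmonized), so the retained records satisfy every instrument-set
    invariant: p < threshold, pairwise r² below the clump threshold where
    known, no palindromes.
    """
    cand = select_candidates(exposure, regions, target_genes, p_threshold, window_bp)
    if not cand.empty:
        pal = cand.apply(
            lambda r: is_palindromic(r["effect_allele"], r["other_allele"]), axis=1
        )
        cand = cand.loc[~pal].reset_index(drop=True)
    kept = clump(cand, ld, r2_threshold) if not cand.empty else cand
    strength = instrument_strength(kept) if len(kept) else None
    provenance = {str(v): "direct" for v in kept["variant_id"]} if len(kept) else {}
    return InstrumentSet(
        class_name=class_name, records=kept, strength=strength, provenance=provenance
    )
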