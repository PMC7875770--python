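"""Strand-collapsed substitution classes and per-component mutational spectra.

SNVs are collapsed onto the six pyrimidine/adenine-reference classes
C>A, C>G, C>T, A>C, A>G, A>T by reverse-complementing purine-reference
(G or T) substitutions together with their trinucleotide context.  C>*
classes are optionally stratified by CpG status: a site is CpG when the
(possibly complemented) reference C is immediately followed by G.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
CLASSES = ["C>A", "C>G", "C>T", "A>C", "A>G", "A>T"]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substitution_class(ref_base: str, alt_base: str,
                       trinucleotide_context: str | None = None):
    """Collapse a substitution to its strand-symmetric class.

    Returns ``(class, cpg_flag)``; ``cpg_flag`` is True/False for
    C-reference classes and None for A-reference classes (CpG status is
    undefined there) or when no context is supplied.
    """
    ref, alt = ref_base.upper(), alt_base.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"non-ACGT allele in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    ctx = trinucleotide_context.upper() if trinucleotide_context else None
    if ctx is not None:
        if len(ctx) != 3 or any(b not in "ACGT" for b in ctx):
            raise ValueError(f"invalid trinucleotide context {ctx!r}")
        if ctx[1] != ref:
            raise ValueError(f"context {ctx} does not centre on ref {ref}")
    if ref in "GT":  # orient onto the A/C-reference strand
        ref, alt = _revcomp(ref), _revcomp(alt)
        ctx = _revcomp(ctx) if ctx is not None else None
    cls = f"{ref}>{alt}"
    cpg = None
    if ref == "C" and ctx is not None:
        cpg = ctx[2] == "G"
    return cls, cpg


def component_spectra(assigned: np.ndarray, records: pd.DataFrame,
                      n_components: int | None = None,
                      stratify_cpg: bool = False) -> pd.DataFrame:
    """Class proportions of hard-assigned singletons, per mixture component.

    ``assigned`` holds 1-based component labels aligned row-for-row with
    ``records`` (columns ref, alt and optionally context).  Components with
    no assigned singletons are emitted with NaN proportions rather than
    silently dropped.
    """
    assigned = np.asarray(assigned)
    if len(assigned) != len(records):
        raise ValueError("assignments and singleton records must align 1:1")
    ctx = records["context"] if "context" in records.columns else None
    labels, cpgs = [], []
    for i, (ref, alt) in enumerate(zip(records["ref"], records["alt"])):
        cls, cpg = substitution_class(ref, alt, None if ctx is None else ctx.iloc[i])
        labels.append(cls)
        cpgs.append(cpg)
    df = pd.DataFrame({"component": assigned, "class": labels})
    keys = ["component", "class"]
    if stratify_cpg:
        df["cpg_flag"] = [
            None if c is None else ("CpG" if c else "non-CpG") for c in cpgs
        ]
        keys.append("cpg_flag")
    counts = (df.groupby(keys, dropna=False).size().rename("count")
              .reset_index())
    totals = counts.groupby("component")["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    k_all = range(1, (n_components or int(assigned.max())) + 1)
    empty = [k for k in k_all if k not in set(counts["component"])]
    if empty:
        pad = pd.DataFrame({
            "component": empty, "class": pd.NA, "count": 0, "proportion": np.nan,
        })
        counts = pd.concat([counts, pad], ignore_index=True)
    return counts.sort_values(keys).reset_index(drop=True)
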