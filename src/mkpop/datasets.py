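"""Bundled count-level dataset: published per-locus MK counts for 54
Daphnia pulex loci (30 putative immune, 24 non-immune) against a
D. parvula or D. arenata outgroup.

Sequence-level reanalysis requires the deposited GenBank alignments; the
count table is sufficient for the single-locus MK tests and the
multilocus alpha estimation, with site exposures approximated from the
sequenced length.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mk_counts import MKTable
from .mk_multilocus import LocusRecord

# fraction of coding sites treated as nonsynonymous when only the
# sequenced length is known (typical Nei-Gojobori exposure split)
DEFAULT_LN_FRACTION = 0.75


def load_locus_counts() -> pd.DataFrame:
    """The bundled 54-locus count table as a DataFrame."""
    ref = resources.files("mkpop") / "data" / "daphnia_locus_counts.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def records_from_counts(
    df: pd.DataFrame,
    ln_fraction: float = DEFAULT_LN_FRACTION,
    haplotypes_per_individual: int = 2,
) -> list[LocusRecord]:
    """Convert a count table to LocusRecords.

    Site exposures are approximated as L_n = ln_fraction * bp and
    L_s = (1 - ln_fraction) * bp unless explicit L_s/L_n columns are
    present.  Sample sizes are phased haplotype counts (two per diploid
    individual).
    """
    if not 0.0 < ln_fraction < 1.0:
        raise ValueError("ln_fraction must be in (0, 1)")
    required = {
        "locus_id", "class", "n_ind_in", "n_ind_out",
        "pn_in", "ps_in", "pn_out", "ps_out", "dn", "ds",
        "include_multilocus",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if not ("bp" in df.columns or {"L_s", "L_n"} <= set(df.columns)):
        raise ValueError("count table needs either a bp or L_s/L_n columns")
    records = []
    for row in df.to_dict("records"):
        if "L_s" in df.columns:
            L_s, L_n = float(row["L_s"]), float(row["L_n"])
        else:
            L_s = (1.0 - ln_fraction) * float(row["bp"])
            L_n = ln_fraction * float(row["bp"])
        records.append(
            LocusRecord(
                locus_id=str(row["locus_id"]),
                gene_class=row["class"],
                mk=MKTable(
                    pn_in=float(row["pn_in"]), ps_in=float(row["ps_in"]),
                    pn_out=float(row["pn_out"]), ps_out=float(row["ps_out"]),
                    dn=float(row["dn"]), ds=float(row["ds"]),
                ),
                L_s=L_s,
                L_n=L_n,
                n_in=haplotypes_per_individual * int(row["n_ind_in"]),
                n_out=haplotypes_per_individual * int(row["n_ind_out"]),
                include_multilocus=bool(row["include_multilocus"]),
            )
        )
    return records


def load_locus_records(multilocus_only: bool = False) -> list[LocusRecord]:
    """Bundled dataset as LocusRecords; ``multilocus_only`` keeps the 47
    loci retained for the multilocus model (single shared outgroup,
    hyperdiverse loci removed)."""
    records = records_from_counts(load_locus_counts())
    if multilocus_only:
        records = [r for r in records if r.include_multilocus]
    return records
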