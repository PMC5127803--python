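"""Published per-region summary statistics for the reference indel survey.

The bundled table holds, for each sequenced region of the 18 *Arabidopsis
thaliana* indel loci (three R-gene loci RGD1-3, twelve single-indel non-R
loci NRD1-12, three compound loci NRD13-15) plus the GenBank-derived Rpm1
and Rps5 junction regions: accession count, aligned length, fixed
substitution and fixed indel counts, the diversity decomposition terms
(pi_t, pi_fixed, D_xy, d_xy) and Tajima's D.  These printed values are
inputs for reproducing the survey's junction-region arithmetic; they are
not recomputed here.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

_COLUMNS = ("type", "locus", "indel_size", "region", "n", "length", "s_n",
            "fixed_indels", "pi_t", "pi_fixed", "D_xy", "d_xy", "tajima_d",
            "n_indels", "source")


def load_reference_stats() -> pd.DataFrame:
    """The bundled per-region statistics table as a DataFrame."""
    path = files("indelpoly.data").joinpath("junction_region_stats.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["NA"])
    assert tuple(df.columns) == _COLUMNS
    return df


def single_indel_junction_rows(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """The 15 junction-region rows of the single-indel sequenced loci
    (RGD1-3 and NRD1-12; excludes the GenBank loci and the compound
    NRD13-15)."""
    if df is None:
        df = load_reference_stats()
    out = df[df["region"].str.endswith("JR")
             & (df["n_indels"] == 1)
             & (df["source"] == "sequenced")]
    assert len(out) == 15
    return out


def junction_row(locus: str, region: str = "JR") -> pd.Series:
    """One junction-region row by locus name."""
    df = load_reference_stats()
    hit = df[(df["locus"] == locus) & (df["region"] == region)]
    if len(hit) != 1:
        raise KeyError(f"no unique row for {locus} {region}")
    return hit.iloc[0]
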