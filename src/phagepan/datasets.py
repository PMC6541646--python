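"""Packaged reference tables.

Two small TSVs ship with the package:

* ``chpc_phages.tsv`` — characteristics of the 55 CHPC *S. thermophilus*
  phages deposited under GenBank MH937457-MH937511: host strain(s),
  cos/pac group, isolation year and country, fermentation product, genome
  size, CDS count, GC%.
* ``rbp_genotypes.tsv`` — the 43-phage analysis subset with its RBP
  phylogeny cluster (I-VII), the host strain per phage, and the host's EPS
  (A-F) and RGP (A-E) genotype letters derived from the *eps*/*rgp* gene
  clusters deposited under MK483529-MK483592.

The second table is the statistical universe for the exact
sampling-without-replacement association tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .association import AssociationInput
from .tables import PhageMetadataRow, read_metadata


def _data_path(name: str):
    return resources.files("phagepan").joinpath("data", name)


def load_phage_metadata() -> list[PhageMetadataRow]:
    """The 55-phage CHPC collection metadata table."""
    with resources.as_file(_data_path("chpc_phages.tsv")) as path:
        return read_metadata(path)


def load_rbp_genotype_table() -> pd.DataFrame:
    """RBP cluster / host strain / EPS / RGP genotype table (43 phages)."""
    with resources.as_file(_data_path("rbp_genotypes.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def rbp_association_input() -> AssociationInput:
    """The genotype table reshaped for :func:`build_association`.

    EPS and RGP letters live in separate genotype namespaces; pick the one
    to test via ``strain_genotypes`` of the relevant kind (see
    :func:`rbp_association_input_for`).
    """
    return rbp_association_input_for("eps")


def rbp_association_input_for(kind: str) -> AssociationInput:
    if kind not in ("eps", "rgp"):
        raise ValueError("kind must be 'eps' or 'rgp'")
    df = load_rbp_genotype_table()
    clusters = dict(zip(df["phage_id"], df["rbp_cluster"]))
    hosts = {row.phage_id: {row.host_strain} for row in df.itertuples()}
    col = f"{kind}_genotype"
    genotypes: dict[str, str] = {}
    for row in df.itertuples():
        letter = getattr(row, col)
        prev = genotypes.setdefault(row.host_strain, letter)
        if prev != letter:
            raise ValueError(
                f"inconsistent {kind} genotype for strain {row.host_strain}"
            )
    return AssociationInput(
        phage_clusters=clusters, phage_hosts=hosts, strain_genotypes=genotypes
    )
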