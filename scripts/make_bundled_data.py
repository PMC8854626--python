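"""Regenerate the data files bundled with the package.

The architecture/CDS files are SYNTHETIC: random chains whose geometry is
calibrated to published collagen IV facts (23 local collagenous regions;
non-collagenous boundary Gly about one tenth of collagenous Gly; 53-exon
CDS; short amino terminus, long NC1 domain).  They are stand-ins for the
real reference chains, whose interruption coordinates are not bundled.
Run from the repository root: python scripts/make_bundled_data.py
"""

from pathlib import Path

from col4gly import synthetic as syn
from col4gly import population as pop
from col4gly.chain_model import write_architecture
from col4gly.io import write_fasta_sequence

DATA = Path(__file__).resolve().parent.parent / "src" / "col4gly" / "data"

CHAINS = {
    # chain id -> (seed, config)
    "synthetic_col4a5_like": (1, syn.ArchitectureConfig()),
    "synthetic_col4a3_like": (11, syn.ArchitectureConfig(carboxyl_terminus_length=233)),
    "synthetic_col4a4_like": (21, syn.ArchitectureConfig(amino_terminus_length=38)),
}

NOTE = (
    "SYNTHETIC chain architecture: randomly generated stand-in calibrated to\n"
    "published collagen IV geometry (23 local collagenous regions, boundary\n"
    "Gly ~1/10 of collagenous Gly). Not the real reference chain."
)


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    for chain_id, (seed, config) in CHAINS.items():
        arch = syn.gen_architecture(config, seed=seed, chain_id=chain_id)
        write_architecture(
            arch,
            DATA / f"{chain_id}.segments.tsv",
            DATA / f"{chain_id}.exons.tsv",
            header_comment=NOTE,
        )
        cds = syn.gen_cds(arch, seed=seed + 1)
        write_fasta_sequence(
            cds, DATA / f"{chain_id}.cds.fasta", name=f"{chain_id} SYNTHETIC CDS"
        )

    pop.write_rate_table(
        pop.default_rate_table(),
        DATA / "rates_neighbour_dependent.tsv",
        comment=(
            "Parametric neighbour-dependent substitution rates:\n"
            "transition/transversion ratio 4, CpG transition boost 10."
        ),
    )

    # The five most frequent boundary Gly missense variants of the X-linked
    # chain in a population database: genotype counts as printed.
    allele_lines = [
        "#X-linked genotype counts for the five most frequent boundary Gly variants",
        "variant\them\thet\thom",
        "Gly953Val\t249\t442\t7",
        "Gly624Asp\t4\t12\t0",
        "Gly626Ser\t2\t3\t1",
        "Gly1074Ser\t4\t3\t0",
        "Gly961Val\t2\t3\t0",
    ]
    (DATA / "gnomad_top5_boundary_alleles.tsv").write_text(
        "\n".join(allele_lines) + "\n"
    )
    print(f"bundled data regenerated under {DATA}")


if __name__ == "__main__":
    main()
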