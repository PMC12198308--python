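"""Generating the synthetic inputs (and the packaged cDNA sequence).

Writes every file dialect the screens consume — kallisto-style abundance
table, feature annotation, variant calls, sample metadata and the 1137-nt
Obelisk cDNA FASTA — into ./synthetic_inputs/.
"""

from pathlib import Path

from obelisktools import (
    SynthAbundanceSpec,
    default_polymorphism_scenario,
    obelisk_sequence,
    synth_abundance,
    synth_variants,
    write_obelisk_fasta,
)
from obelisktools.rank_abundance import write_abundance_tsv
from obelisktools.synthetic_data import annotation_from_table, write_annotation_tsv
from obelisktools.variant_screen import write_metadata_tsv, write_variant_tsv

outdir = Path("synthetic_inputs")
outdir.mkdir(exist_ok=True)

table = synth_abundance(SynthAbundanceSpec(planted_rank=1, seed=0))
write_abundance_tsv(table, outdir / "abundance.tsv")
write_annotation_tsv(annotation_from_table(table), outdir / "annotation.tsv")

spec = default_polymorphism_scenario(seed=0)
write_variant_tsv(synth_variants(spec), outdir / "calls.tsv")
write_metadata_tsv(list(spec.meta), outdir / "metadata.tsv")

fasta = write_obelisk_fasta(outdir / "obelisk_ss.fasta")
print(f"wrote {sorted(p.name for p in outdir.iterdir())}")
print(f"cDNA length: {len(obelisk_sequence())} nt "
      f"(alphabet {sorted(set(obelisk_sequence()))})")
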