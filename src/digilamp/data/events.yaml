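# Bundled assay registry: maize genome, seed tissue model and GM events.
# Multiplicities are targets per transgene locus: Bt11 carries two copies of
# both the 35S promoter and the NOS terminator; NK603 has one 35Sp-driven
# cassette of two, both NOSt-terminated; Mon810 has lost its NOSt sequence.
genome:
  name: maize
  haploid_size_bp: 2400000000
  haploid_mass_pg: 2.6
  molar_mass_per_bp: 650.0

seed_tissue:
  tissues:
    embryo:
      ploidy: 2
      paternal_genomes: 1
      dna_mass_fraction: 0.5
    endosperm:
      ploidy: 3
      paternal_genomes: 1
      dna_mass_fraction: 0.5

events:
  Bt11:
    event_name: Bt11
    zygosity: hemizygous
    transgenic_parent: male
    target_multiplicity:
      35Sp: 2
      NOSt: 2
  NK603:
    event_name: NK603
    zygosity: hemizygous
    transgenic_parent: male
    target_multiplicity:
      35Sp: 1
      NOSt: 2
  Mon810:
    event_name: Mon810
    zygosity: hemizygous
    transgenic_parent: male
    target_multiplicity:
      35Sp: 1
      NOSt: 0
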