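# Two-genotype synthetic run exercising every stage.
#
# The hic block simulates a wild-type map (decay exponent alpha = 1.0)
# and a mildly decondensed mutant (alpha = 0.7, shallower decay, less
# short-range contact), balances both, and compares per-chromosome
# compactness. The deg block simulates two gene sets with a planted
# overlap and tests its enrichment; the morphology block renders two
# groups of elliptical nuclei and compares area and circularity.
run_name: two-genotype-demo
seed: 7
output_dir: scratch/pipeline_demo

hic:
  simulate:
    genotypes:
      wildtype: {alpha: 1.0}
      mutant: {alpha: 0.7}
    chrom_lengths: {chrA: 2500000, chrB: 2000000}
    bin_size: 10000
    depth: 1000000
    territory_strength: 0.05
  window: 200000
  s_max: 2500000

deg:
  simulate:
    universe_size: 5000
    size_a: 400
    size_b: 300
    overlap: 120

morphology:
  simulate:
    image_shape: [420, 420]
    groups:
      wildtype:
        ellipses:
          - [70, 70, 32, 30, 0.0]
          - [70, 210, 35, 28, 0.4]
          - [70, 350, 30, 30, 0.0]
          - [210, 70, 33, 29, 1.0]
          - [210, 210, 31, 27, -0.5]
          - [210, 350, 34, 30, 0.2]
      mutant:
        ellipses:
          - [350, 70, 26, 22, 0.0]
          - [350, 210, 24, 20, 0.6]
          - [350, 350, 25, 21, -0.3]
          - [140, 140, 23, 20, 0.8]
          - [280, 140, 26, 21, 0.0]
          - [280, 280, 24, 22, 1.2]
  pixel_size: 0.1
  min_area: 100
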