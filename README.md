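# hippogen

Paleogenomic introgression analyses for the hippotragin antelope quartet —
the extinct blue antelope (*Hippotragus leucophaeus*), sable (*H. niger*),
roan (*H. equinus*) and the scimitar-horned oryx outgroup — built for
low-coverage, damage-afflicted ancient genomes, together with a
multispecies-coalescent + aDNA-damage simulator so that every stage is
verifiable against known truth without any external data.

## What it computes

- **Simulation** (`hippogen.simcore`): per-window coalescent genealogies on
  the species tree `(((blue, sable), roan), outgroup)` with incomplete
  lineage sorting and an optional introgression pulse (donor, recipient,
  time, proportion *f*); finite-site K2P mutation; an ancient-DNA
  observation model (Poisson coverage, terminal C→T deamination decaying as
  `delta_ss·e^(-lambda·p)` from both fragment ends, uniform G→T oxidation,
  base error) emitting per-site base counts plus full truth.
- **Pseudohaploid calling** (`hippogen.consensify`): Consensify-style
  majority-of-3 calls and random-read sampling, with min/max depth masking
  (`max_depth` defaults to twice the mean depth).
- **D statistic** (`hippogen.dstat`): transversions-only ABBA-BABA,
  `D = (nABBA − nBABA)/(nABBA + nBABA)`, with a weighted block jackknife
  (1-Mb blocks) for the standard error and Z score; `|Z| > 3` significant.
- **Window phylogenies** (`hippogen.windowphylo`): non-overlapping windows
  (20 kb windows, 80 kb gaps by default), transversion p-distances via RY
  coding, neighbor-joining trees, topology classes BS/BR/RS and gene/site
  concordance factors.
- **Gene-flow direction and timing** (`hippogen.direction`): the
  roan–sable path length as a proportion of tree length, filtered to
  [0.0002, 0.9], compared between species-topology and discordant windows
  via a permutation median test plus Hartigan's dip test; with two roan
  individuals, blue's attachment point (outside vs inside the roan pair)
  dates the flow relative to the roan MRCA.
- **Diversity** (`hippogen.diversity`): damage-aware pairwise differences
  (clean A/T and C/G transversions only) over a jointly filtered site set
  with a single shared denominator, plus substitution spectra and a
  simulation-truth heterozygosity oracle.
- **Mitochondrial statistics** (`hippogen.mitodiv`): ambiguity-free column
  filtering, segregating sites, nucleotide diversity, pairwise matrix.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Run the full synthetic pipeline (simulate → call → D statistic → window
trees → direction) on a small introgression scenario:

```sh
cat > example.yaml <<'YAML'
seed: 7
stages: [simulate, call, dstat, windows, direction]
n_windows: 400
window_length: 5000
model:
  mu: 2.5e-08
  pop_size: {blue: 25000, sable: 25000, roan: 25000, outgroup: 25000,
             bs_anc: 25000, bsr_anc: 25000, root: 25000}
  pulse: {donor: roan, recipient: blue, time: 150000, proportion: 0.2}
damage: {coverage: 5.0}
dstat: {block_size: 250000}
direction: {min_windows: 20}
YAML
hippogen run-all --config example.yaml --out runs/example
```

which prints (abridged):

```
{
 "simulate": {"n_windows": 400, "topology_counts": {"BS": 330, "BR": 64, "RS": 6}},
 "call": {"mode": "consensify", "individuals": ["blue_0", "outgroup_0", "roan_0", "sable_0"]},
 "dstat": {"D": 0.9110169491525424, "SE": 0.03177798744690142, "Z": 28.66817638073468},
 "windows": {"n": 400, "summary": {"BS": 0.7825, "BR": 0.1825, "RS": 0.035, "other": 0.0}},
 "direction": "roan_to_blue"
}
```

Reading the output: the roan→blue pulse (f = 0.2) inflates the blue+roan
discordant class far beyond its mirror image (window trees: BR 18.3% vs
RS 3.5%; under pure incomplete lineage sorting the two would be equal),
and the D statistic is strongly positive (D = 0.91 with Z = 28.7 ≫ 3:
excess derived-allele sharing between blue and roan — in this low-ILS
demography nearly every informative site traces to the pulse, hence the
extreme D). The branch-length test then infers the direction: roan–sable
distances in BR windows match those in species-topology windows
(unimodal, equal medians), which is the roan→blue signature. Every output
file, with checksums, is listed in `runs/example/manifest.json`.

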