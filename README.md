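# synmatch

Quantitative analysis of synaptic partner matching in the fly olfactory
system: a tested Python implementation of the statistics behind
proximity-labeling interactome screens and single-axon developmental
imaging.

In the antennal lobe, each olfactory receptor neuron (ORN) type's axons
synapse with one projection neuron (PN) type's dendrites inside a single
glomerulus. Two kinds of quantification drive studies of how that
specificity arises:

1. **Interactome filtering.** A bait transmembrane protein (e.g. the
   teneurin Ten-m) is fused to a proximity-labeling enzyme; labeled
   proteins are quantified by six-plex TMT against a membrane-anchored
   spatial reference (SR) and a negative control (NC). Per protein the
   log2 TMT ratio is modelled as `log2ratio = b0 + b1·TRT + b2·SR` with
   NC baseline; the bait/NC fold change is `b1` and the bait/SR fold
   change the contrast `b1 − b2`. Variances are moderated with an
   empirical-Bayes prior `(d0, s0²)` estimated across proteins, contrasts
   tested with moderated t statistics, and p-values BH-FDR adjusted. A
   three-step filter (unique peptides ≥ 2; fold change over NC ≥ the
   bait's own; fold change over SR > 0) yields the bait's intracellular
   interactome, ranked by bait/SR fold change.
2. **Imaging quantification.** Volume-overlap indices between segmented
   axon and dendrite channels (match = |A∩D|/|D|, mismatch = |A∩D|/|A|,
   mistarget = intensity ratio between glomeruli); single-axon
   morphometry on SWC traces (stem axon = thickest root-to-leaf path,
   developmental stage from stem length, normalized primary-branch
   positions, PN-contact and multifurcation calls, branch densities,
   group statistics); and F-actin density profiles along traced branches
   (per-axon min-max-normalized intensity per μm of arc length, compared
   between and within branches).

Every stage has a seed-deterministic synthetic generator
(`synmatch.simulate`) that plants known truth — interactors and
contaminant classes in TMT tables, programmed ellipsoid overlaps, branch
positions/contacts and contact-zone intensity boosts — so the whole
pipeline is testable end to end without any external data.

## Worked example

```python
import synmatch as sm

# synthetic six-plex TMT screen: 2000 proteins, 50 planted interactors,
# 200 membrane-background, 100 endogenously biotinylated contaminants
table, truth = sm.gen_tmt_dataset(sm.TmtSimConfig(seed=1))
result = sm.run_interactome(table, sm.default_design(), bait_id="BAIT")
print(result.trace)
print(result.shortlist[["rank", "protein_id", "fc_sr", "q_sr"]].head())
```

```
FilterTrace(bait_id='BAIT', n_detected=2001, n_step1=1914, n_step2=251,
            n_step3=144, bait_fc_nc=1.3375750177325856)
   rank protein_id     fc_sr          q_sr
0     1     P00019  2.607251  1.077630e-09
1     2     P00003  2.478098  1.077630e-09
2     3     P00010  2.398301  1.672989e-09
3     4     P00049  2.392009  1.199642e-09
4     5     P00044  2.348212  1.555595e-09
```

Of 2001 detected proteins, 1914 have ≥ 2 unique peptides, 251 are at
least as NC-enriched as the bait itself, and 144 survive the strict
spatial-reference filter; the top-ranked candidates are all planted
interactors (true bait/SR fold change 2, recovered ≈ 2.3–2.6 at this
seed's noise draw). The same objects work from the shell:
`synmatch simulate tmt --seed 1 --out sim/ && synmatch interactome
--quant sim/quant.tsv --bait BAIT --out out/`.

Volumetric and morphometric stages run the same way:

```python
axon, dendrite, vtruth = sm.gen_glomerular_volumes(sm.VolumeSimConfig(overlap_fraction=0.4, seed=2))
m = sm.match_index(sm.segment_volume(axon), sm.segment_volume(dendrite))
print(round(vtruth["match_index"], 4), round(m, 4))   # 0.3997 0.3996

sim = sm.gen_axon_with_field(sm.AxonSimConfig(stage=3, seed=3))
ann = sm.annotate_stem(sim.tree, sim.regions)
print(ann.stage, round(ann.stem_length, 1))           # 3 186.0
```

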