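# crevalid

Computational validation toolkit for Cre knock-in rodent lines (e.g.
D1-Cre and A2a-Cre rat lines targeting striatal medium spiny neurons).
When a new driver line is made, three independent questions need
quantitative answers:

1. **Is Cre transcribed in the right cells?** Multiplexed single-molecule
   FISH (RNAscope) renders individual mRNAs as fluorescent puncta.
   `crevalid` segments DAPI nuclei, detects puncta per probe channel,
   calls each nucleus positive or negative against a Poisson background
   threshold, and summarizes co-expression as *specificity* (% of iCre+
   nuclei that are also receptor-probe+) and *consistency* (% of
   receptor-probe+ nuclei that are also iCre+), plus per-cell count R².
2. **Is the cassette inserted once, in the right place?** From paired-end
   whole-genome alignments against a reference augmented with the
   cassette contig, `crevalid` selects read pairs with one mate anchored
   in the cassette (≥100 bp aligned), clusters the genome-side mates into
   insertion loci, and issues a single-copy verdict. A companion screen
   classifies predicted CRISPR off-target sites by comparing variant
   calls between two lines: changes shared by both lines are strain
   background, line-specific changes at predicted sites are candidate
   off-target events.
3. **Can Cre+ neurons be identified in vivo?** For opto-tagging,
   `crevalid` applies three criteria to each recorded unit: a
   window-resampling latency test on 10-ms post-laser spiking
   (p < 0.001), a z-scored PSTH peak > 10 for both 5- and 10-ms pulses,
   and Pearson r > 0.9 between light-evoked and session-wide waveforms.

Because real micrographs, sequencing runs, and recordings for a new line
are rarely public, every stage ships with a synthetic-data generator
(`crevalid.synthetic_data`) that plants known ground truth — nuclei,
per-cell puncta counts with a configurable joint co-expression structure,
cassette-anchored read pairs, photo-responsive units — so the whole
pipeline is testable end to end.

## The positivity model

A nucleus with dilated area $A$ px is called positive for a probe when
its puncta count $c$ strictly exceeds the threshold $k$, the smallest
integer with

$$F_\text{Pois}(k;\ \lambda_0 A) \ge 0.95,$$

where $\lambda_0$ is the field-wide background puncta rate per pixel
measured outside all (dilated) nuclei. Specificity and consistency are
then simple conditional percentages over the called table.

## Worked example

```python
import crevalid as cv
from crevalid.io import Manifest
from crevalid.workflows import quantify_fish_image

spec = cv.CoexpressionSpec.from_rates(p_target=0.5, consistency=0.8,
                                      specificity=0.9)
image, truth = cv.simulate_fish_image(n_cells=150, image_shape=(1024, 1024),
                                      coexpression_spec=spec, seed=11)
manifest = Manifest(sample_id="demo", line="D1-Cre", region="DS", image="")
called, summary = quantify_fish_image(image, manifest)
print(f"n_cells={summary.n_cells}  specificity={summary.specificity:.1f}%  "
      f"consistency={summary.consistency:.1f}%")
print(f"off-target: {summary.offtarget_specificity:.1f}% / "
      f"{summary.offtarget_consistency:.1f}%")
```

prints (planted specificity/consistency were 90%/80%; the off-target
probe is planted nearly segregated from the target):

```
n_cells=163  specificity=92.4%  consistency=77.2%
off-target: 9.1% / 8.1%
```

The estimates track the *realized* planted rates of this 150-cell sample
(92.1% / 78.4%) to within ~1.2 percentage points; the residual gap is
detection bias (merged puncta, imperfect nuclear boundaries), quantified
in `docs/methods.md`.

The same stages are available from the shell:

```bash
crevalid simulate fish --n-cells 150 --seed 11 --out scene/
crevalid quantify --manifest manifest.yaml --seed 11 --out results/
crevalid locate-insert --sam reads.sam --cassette-name iCre_cassette \
    --expected chr1:100000 --out insertion/
crevalid offtarget-screen --sites sites.csv --out screen.json
crevalid optotag --spikes spikes.csv --stims stims.csv --seed 1 --out tags.json
```

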