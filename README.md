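# stimscreen

Analysis pipeline for **multiplex bead-immunoassay (Luminex/xMAP) stimulus
screens**: experiments in which cultured cells in 96-well plates are exposed
to a large library of stimuli (cytokines, growth factors, lipids, drugs, TLR
ligands) and the response of each well is read out as median fluorescence
intensities (MFI) over an antibody panel — intracellular phosphoproteins at
short timepoints, secreted factors after a day. The package is written for
bench scientists and bioinformaticians who need to turn such plate tables
into activation calls and stimulus groupings reproducibly.

## What it computes

Given raw per-well MFI values with design metadata, the pipeline is:

1. **Normalization** (`normalize`). For every signal *s* (analyte × panel ×
   timepoint) the unstimulated baseline is the **median over the medium-only
   control wells**, pooled across the plates of that (panel, timepoint)
   group. The response of stimulus *x* is the fold change

   FC(x, s) = m(x, s) / median{ m(c, s) : c control wells },

   where m(x, s) is the single stimulated measurement or the median over
   replicate wells.

2. **Activation calling** (`activation`). A cell is *active* when
   FC ≥ t, with t = 1.5 by default; a sensitivity analysis over a threshold
   grid (1.05–3.0, step 0.05) reports the percentage of active cells and its
   discrete slope so the user can verify t sits on the insensitive plateau.
   Multi-timepoint phosphoprotein signals can be OR-collapsed: an analyte is
   active if it crosses the threshold at **at least one** timepoint.
   Stimuli activating nothing, then signals responding to nothing, are
   filtered out; per-stimulus and per-signal hit counts are tabulated.

3. **Clustering** (`cluster`). Pairwise stimulus dissimilarities are
   **Gower's coefficient on the binary profiles** — with all-binary
   symmetric variables this is the simple-matching distance
   d(i, j) = (# signals where the calls differ) / (# signals compared); an
   asymmetric (Jaccard-style) mode discarding 0/0 matches is provided.
   Stimuli are then grouped by **DIANA divisive hierarchical clustering**:
   starting from one all-inclusive cluster, the cluster with the largest
   diameter is repeatedly split via the splinter-group procedure, each split
   recorded at the diameter of the cluster it divides; the tree is cut into
   k clusters (default 3).

4. **qPCR validation arithmetic** (`qpcr_stats`). ΔCq = Cq(gene) −
   Cq(reference), Livak fold changes 2^−ΔΔCq against the mean control ΔCq,
   relative abundances 2^−ΔCq, and a normality-routed group comparison
   (Shapiro–Wilk → Welch ANOVA + Dunnett / t-test / Welch-t /
   Mann–Whitney / Kruskal–Wallis) with a full routing trace.

Because raw screens of this kind are rarely deposited, the package ships a
first-class **synthetic-data generator** (`synthetic_data`) that emulates
the design — 27 phosphoproteins × {5 min, 25 min}, 32 secreted factors ×
{24 h}, five pooled medium controls spread over two plates per group,
log-normal multiplicative noise — with planted, cluster-structured
activation profiles and full ground truth, so every stage is testable end
to end.

## Worked example

```bash
stimscreen simulate --seed 5 -o sim/
stimscreen normalize sim/screen.tsv -o fc.tsv
stimscreen call fc.tsv -t 1.5 --filter -o act.tsv
stimscreen hits act.tsv | head -6
stimscreen cluster act.tsv -k 3 -o clusters.tsv --tree tree.json
```

prints

```
simulated 120 wells (6 plates, 35 stimuli) into sim/
wrote 35 x 86 fold changes to fc.tsv
wrote 30 x 69 calls (threshold 1.5, >=) to act.tsv
# activations per stimulus
              phospho  secreted  total
stimulus_030       24        13     37
Activin A          22        14     36
stimulus_027       23        13     36
cut 30 stimuli into 3 clusters (divisive coefficient 0.953); wrote clusters.tsv
```

Reading: of 35 simulated stimuli, 5 activated nothing and were filtered
(35 → 30 rows), and 17 of the 86 signals never responded (86 → 69 columns).
The hit table ranks stimuli by total activations split by panel. The
divisive coefficient 0.953 (0–1) says the division heights are strongly
structured — consistent with the three planted clusters the cut recovers.

The same steps are available as library calls
(`simulate_screen`, `fold_changes`, `call_activations`, `filter_matrix`,
`gower_binary`, `diana`, `cut_tree`); see the docstrings and
`docs/methods.md`.

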