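# lesionrefine

Interactive skin-lesion segmentation for dermoscopy, as a two-stage pipeline:

1. **SBox stage** — the user draws a loose *surrounding box* around the
   lesion; a fully convolutional network segments the cropped region,
   producing coarse logits `B`.
2. **Click stage** — if the result needs fixing, the user adds *positive*
   clicks on missed lesion pixels and *negative* clicks on wrongly included
   ones. Clicks are encoded as Gaussian distance maps
   `G(m,n) = max_clicks exp(-4 d² / R²)`, fed (with cached stage-1 features —
   the encoder runs once per session) to a lightweight refinement head that
   outputs correction logits `C`, and fused residually:

   ```
   F = W ∗ C + B,     W(m,n) = Σ_clicks exp(-4 d² / R_w²),  R_w ≫ R
   ```

   so corrections act only where clicks grant weight; with no clicks,
   `F ≡ B` exactly.

Training simulates the user: boxes are ground-truth tight boxes jittered by
up to ±30 px per edge, and clicks are sampled uniformly from the false
negatives / false positives of the current coarse prediction. The click head
is trained only on *hard* objects (coarse IoU < 0.9), with the coarse stage
frozen, under momentum SGD and the poly schedule
`lr = base_lr (1 − iter/max_iter)^0.9`. Evaluation reports pixel-wise
accuracy, sensitivity, specificity, Dice and IoU
(`Dic = 2·IoU/(1+IoU)`).

The package is pure scientific Python (NumPy/SciPy networks with
hand-written backprop, <100 k parameters by default) and ships a synthetic
dermoscopy-like data generator, so the whole pipeline trains and evaluates
on one CPU in minutes with no downloads. Real data (8-bit RGB PNGs with
0/255 single-channel PNG masks, e.g. ISIC or PH2 exports) drop in through
the same manifest format. See `docs/methods.md` for the full model
description.

## Worked example

```bash
# 300 synthetic 96-px samples with distractor artifacts
lesionrefine synth --n 300 --size 96 --artifact-prob 0.5 --seed 1 --out data/

# stage 1: coarse training (20 epochs, desk scale)
lesionrefine --seed 1 train-sbox --data data/ --epochs 20 --out sbox.npz

# stage 2: mine hard objects, train the click head on them
lesionrefine --seed 1 mine-hard --data data/ --checkpoint sbox.npz --out hard.json
lesionrefine --seed 1 train-click --data data/ --checkpoint sbox.npz \
    --hard-ids hard.json --epochs 10 --out model.npz

# coarse vs 2-click refined metrics
lesionrefine --seed 1 eval --data data/ --checkpoint model.npz --clicks 2 --out report.csv
```

This run mined 127 of the 300 objects as hard (coarse IoU < 0.9); the
`eval` command then prints a three-row summary over the dataset (guidance
radii default to R = 15, R_w = 45 at the 96-px crop):

```
        stage      acc      sen       spe      dic      iou
         sbox 0.915894 0.901863  0.951624 0.934684 0.882774
sbox+click(2) 0.921064 0.914139  0.939687 0.939490 0.890493
        delta 0.005170 0.012276 -0.011937 0.004806 0.007719
```

read: two simulated clicks per object lift mean IoU from 0.883 to 0.890
and Dice from 0.935 to 0.939; sensitivity rises because positive clicks
recover missed lesion rim, at a small specificity cost. Gains concentrate
on the hard objects — the clicks-to-target and acceptance protocols below
quantify that. A
single image can be refined interactively with
`lesionrefine refine --image img.png --box box.json --clicks clicks.json
--checkpoint model.npz --out mask.png`, and
`lesionrefine clicks-to-target --iou 0.9` reports the mean number of
interactions (box = 2 clicks, then one per step) needed to reach an IoU
target. `lesionrefine ablate` compares the ASPP / PSP / naive
global-context variants under identical seeds.

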