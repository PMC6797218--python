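# Methods

## The measurement model

A scene represents one imaged field of a fixed ventricular single-cell
suspension with four channels: DNA stain (DAPI), a cardiomyocyte marker
(cTnT-like), an endothelial marker (CD31-like), and a fixable live/dead
stain. The quantification proceeds in five stages.

**Nucleus segmentation.** The DNA channel is thresholded globally (Otsu by
default, or a fixed value to reproduce a same-threshold-for-all-samples
protocol), connected components below a minimum area are discarded, and
components containing multiple seed maxima of the (lightly smoothed)
distance transform are split by watershed. Seed maxima must be at least one
expected nucleus radius apart, which keeps round nuclei from being
oversplit while separating touching pairs.

**Integrated fluorescence.** Per-nucleus DNA content is carried by the
integrated signal: the sum of background-subtracted intensity over the
nucleus mask, where background is the median of all non-nucleus pixels of
the image. Masks are dilated by 2 px before summation so the PSF-blurred
tails are captured; both 2N and 4N nuclei would otherwise lose the same
signal fraction, but dilation reduces sensitivity to exactly where the
threshold cuts the blurred profile. Negative totals clamp to zero with a
flag.

**Cell grouping and typing.** Cells are delineated either by the
generator's ground-truth mask or by labelling connected components of the
union of thresholded marker channels. Marker and live/dead thresholds
default to max(Otsu, background median + 6 robust sigmas); the floor
prevents Otsu from splitting pure camera noise when a channel has little or
no lit area (e.g. the live/dead channel of an all-alive field). A nucleus
belongs to the cell whose label contains its centroid — labels partition the
plane, so no tie-break is needed. A cell is CM if its CM-marker mean exceeds
both its threshold and the EC-marker mean (EC symmetrically), otherwise
"other"; it is alive if its live/dead mean is below threshold. Cells without
nuclei and nuclei outside every cell are excluded with logged counts.
Nucleation above 4 is binned as "4+" to mirror mono/bi/tri/tetra reporting.

**Ploidy calling.** Endothelial nuclei are presumed diploid, so the median
of their integrated signal defines normalized value 1.0; at least 30
endothelial nuclei are required (configurable) or the run errors. Classes
are assigned at √2 (2N vs ≥4N) and optionally 2√2 (4N vs ≥8N) — the
geometric midpoints of 1–2 and 2–4 — because under multiplicative lognormal
noise the misclassification probability is then symmetric between
neighbouring classes. Boundary ties go to the higher class, a fixed and
documented rule. At the default noise level (CV 0.15) the expected
mislabel rate per nucleus is below 1%.

**Summaries and comparison.** Per heart: nucleation fractions over viable
CMs, the diploid fraction among mononuclear-CM nuclei, and the
mononuclear-diploid percentage, reported both as the product
mono% × P(2N|mono) and as a direct count; the product form is primary
because composition figures are conventionally quoted that way, and the two
coincide whenever every mononuclear CM contributes exactly one called
nucleus. A QC flag applies the ≥600-cells-per-heart rule. Groups of hearts
are compared with an unpaired two-tailed Student t-test on per-heart values
(pooled variance, df = n₁+n₂−2), with Welch's form as an explicit option;
per-heart (not pooled) fractions are the experimental unit, matching
per-animal analyses. Two groups with zero variance and equal means give
t = 0, p = 1.

## The synthetic generator

Each cell is a disk; its nuclei are disks placed at the centre (mononuclear)
or on a ring (2–4 nuclei), with a minimum clearance of 2 px between sibling
nuclei and 6 px between cells. Cell placement is rejection sampling with a
spatial grid; an explicit error names the areal density when placement
fails. Nuclear integrated DNA signal is drawn as

```
I = (copy_number / 2) × base_2n_intensity × LogNormal(mean 1, CV)
```

and painted uniformly over the nucleus disk so that the painted sum equals
the draw exactly; the whole channel is then blurred with a Gaussian PSF,
and background plus Gaussian camera noise is added before clipping to
16 bits (saturation is flagged; defaults avoid it). Marker channels are lit
over the corresponding cell masks and the live/dead channel over dead
cells, which are otherwise morphologically normal — dead cells are excluded
by stain only, as in the protocol being emulated.

Defaults: base 2N intensity 6000 counts, intensity CV 0.15, nucleus radius
4.0 ± 0.4 px, cell radius 13 ± 1.5 px (raised per cell when needed to fit
its nuclei — multinucleated cells are accordingly slightly larger), PSF
σ = 1 px, background 100 ± 5 counts, dead fraction 0.10, pixel size
0.5 µm (metadata only). Scene density is planned at ~22% areal packing.

Presets fix the composition parameters: *H. glaber* — 30% mononuclear /
70% binucleated, mononuclear nuclei 23% 2N / 77% 4N; C57BL/6J — 95%
binucleated with nucleation (4, 95, 0.8, 0.2)% and mononuclear nuclei 50%
2N, giving the ~2% mononuclear-diploid level typical of this strain; A/J —
nucleation (12, 85.5, 2, 0.5)% with mononuclear nuclei 83.33% 2N, giving
the reported 10% mononuclear-diploid level. The C57BL/6J and A/J
mononuclear-ploidy splits and the multinucleated-nucleus split (95% 2N /
5% 4N in all presets) are not printed quantities; they were fixed once at
values consistent with the reported strain levels and with binucleated-CM
nuclei being predominantly diploid. Residual polyploid mass, where any,
sits on 4N; ≥8N exists in the class system but is rare and the presets give
it zero mass.

**What the generator does not emulate:** rod-shaped CM morphology, debris
and cell clumping, uneven illumination, chromatin texture, nuclear size
scaling with ploidy, 3D effects, and spectral bleed-through. Passing the
recovery tests therefore shows that the measurement chain is unbiased for
well-separated disk-like cells under multiplicative intensity noise — not
that it would survive clumped or overlapping real material. The nucleation
and ploidy measurements are also unified here on one simulated image set,
whereas the emulated protocol counted nucleation by eye and measured ploidy
on separately scanned slides.

## Sequence-consequence module

Coordinates are 1-based inclusive genomically and 1-based from the spliced
transcript start; the CDS is anchored at `cds_start`. Minus-strand genes are
reverse-complemented at model load, after which all logic is
transcript-oriented. Edits are expressed in pre-edit transcript coordinates
and applied right-to-left so positions never need remapping; overlapping
edits are an error. Junction bookkeeping: a skipped exon's junctions vanish,
a retained intron erases its junction, and a shifted donor site's junction
moves with the new exon end. A length-changing edit spanning the CDS anchor
is an error.

Translation walks codons from the anchor to the first stop.
`last_intact_residue` is the longest protein prefix matching the reference;
the frameshift flag is pure frame arithmetic (net CDS length change mod
3 ≠ 0); `ectopic_codon_count` counts residues after the intact prefix and
before the stop, and is defined as 0 for in-frame variants — so a
frameshift "terminating one amino acid later" has count 1. Transcripts with
no stop are flagged nonstop. NMD defaults to the rule that any stop 5′ of
the final exon–exon junction triggers decay; the literature 50-nt rule is an
explicit mode, never silently applied. Molecular weights use average
(not monoisotopic) residue masses plus one water (18.02 Da), matching
SDS-PAGE-style predicted sizes; reports carry both the MW of the full
truncated product and of the intact prefix alone, since predicted truncation
sizes are quoted both ways. Masses are reported in kDa and rounded only for
display.

## Numerical and design choices

- All randomness flows from `numpy.random.default_rng`; experiments spawn
  per-heart child seeds via `SeedSequence([root, index])` (kept below 2³¹),
  so hearts are independent and runs reproduce bit-identically per seed.
- Otsu is the default DNA threshold because the emulated protocol specifies
  only a "standard threshold for all samples": the default must be
  parameter-free, and the fixed-value option reproduces literal sameness.
- Minimum nucleus area defaults to the area of a disk of half the expected
  nucleus radius — rejects specks without touching real nuclei.
- The 2N/≥4N boundary is a choice of this package: no numeric cutoff is
  published for the DNA-intensity analysis being emulated. √2 is the
  variance-symmetric choice under multiplicative noise.
- Pooled (not per-animal-averaged) nucleus fractions are the default for
  the ≥4N-among-mononuclear figure; per-heart values are also emitted, so
  either convention can be computed.
- Degenerate inputs error loudly and specifically: zero-area images, empty
  masks, too few endothelial nuclei (count named), zero endothelial median,
  impossible placement density (density named), groups of fewer than two
  hearts, non-positive normalized intensities.

## Problem sizes

The recovery analyses simulate 5 hearts × 800 CMs + 100 endothelial cells
per preset — comfortably above the 600-cell QC rule and enough for
sub-point binomial standard errors — and the null-calibration and power
simulations use 200 replicates of 5-vs-5-heart comparisons at the same
per-heart size, run through the generator's truth path (identical
composition sampling without pixel rendering). Recovered figures are held
to within three standard errors of the generator parameters, using the
larger of the across-heart SEM and the pooled binomial SE.

## Known limitations

- Touching nuclei are split by distance-transform watershed; heavily
  overlapping nuclei (not produced by the generator) would undercount
  nucleation and bias mono% upward.
- The marker-derived cell mask relies on cells being spatially separated;
  confluent or clumped preparations would need the ground-truth-mask path
  or a dedicated instance-segmentation front end.
- The endothelial diploid standard assumes endothelial nuclei are not
  themselves cycling; a preparation rich in S/G2 endothelial cells would
  inflate the standard and deflate all normalized values.
- `run_experiment` compares exactly two groups, as in per-figure pairwise
  analyses; no multiple-testing machinery is included.
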