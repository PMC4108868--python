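# halometry

A headless, scriptable implementation of the **Halo test** — a
psychophysical halometer that quantifies night-vision disturbances such
as halos, glare and starbursts. The observer fixates a bright central
disc on a dark screen and clicks whenever a faint peripheral spot
flashes nearby; an observer who perceives a halo around the glare source
misses the spots closest to it. The package is for vision scientists and
ophthalmic researchers who want the test's geometry, scheduling, scoring
and analysis as reproducible library code rather than an interactive GUI
— including a simulated-observer model so entire studies can be run and
validated without human subjects.

## The index

A session presents each of N peripheral stimuli p times. With r_i the
distance (pixels) from the centre of the main stimulus to stimulus i,
and p_i the number of its presentations the observer missed, the
**visual disturbance index** is

```
VDI = Σ_i p_i · r_i²  /  ( p · Σ_i r_i² )
```

VDI ranges from 0 (everything detected) to 1 (nothing detected); a miss
far from the glare source — where detection should be easy — costs more
than one close in. Its complement, the visual discrimination index,
is VDiscI = 1 − VDI.

The default configuration is the reference protocol: a 25 px central
disc and 1 px peripheral spots on 18 semiaxes with 4 rings, the rings
falling at 26, 38, 49 and 60 px (innermost tangent to the disc, equal
spacing to the maximum radius, fractional positions rounded up); each
spot shown twice (p = 2, so 144 trials), 1 s exposure, randomized
0.8–2 s blank gaps, after 3 min dark adaptation plus 1 min adaptation to
the central stimulus, viewed from 2.5 m on a 1024 × 768 screen.

## Worked example

Simulate one observer whose halo swallows stimuli out to ~40 px, score
the session, and draw the detection map:

```python
import halometry as h

layout = h.generate_layout(None)                 # reference protocol, 72 stimuli
schedule = h.build_schedule(layout, seed=7)      # 144 randomized timed trials
observer = h.ObserverModel(halo_radius_px=40, slope=0.25)
clicks = h.simulate_session(schedule, observer, seed=8)
matrix = h.match_responses(schedule, clicks)
result = h.score_session(matrix, layout)
print(f"VDI = {result.vdi:.4f}   expected = {h.expected_vdi(observer, layout):.4f}")
print(h.render_text_map(result, width=45))
```

prints

```
VDI = 0.2264   expected = 0.2337
                  2       2
           2                     2
                   2     2
             1                 2
     2              X   1              2
        2      X             X      2
                    X   X
 2         1     X         X     2         2
     2         X             X         2
         X   X                 X   1

2   2   X   X         O         X   1   1   2

         X   X                 X   1
     2         X             X         2
 2         1     X         X     X         2
                    X   X
        1      1             1      2
     2              2   X              2
             2                 2
                   2     2
           2                     2
                  2       2
rho (VDI) = 0.23
```

The central disc is `O`; a digit is the number of times that stimulus
was detected (out of 2), `X` marks a never-detected stimulus. The ring
of X marks around the centre is the simulated halo: the observed VDI of
0.23 sits within Monte-Carlo noise of the model's closed-form
expectation of 0.23. `render_figure` produces the same map as a
green/red PNG or SVG, and `halo_extent` returns the per-semiaxis radius
of the contiguous fully-missed core — the halo's shape.

The same steps are available from the shell:

```
halo schedule --seed 7 --out schedule.csv
halo match --schedule schedule.csv --clicks clicks.csv --out matrix.csv
halo score --matrix matrix.csv --render map.png
halo simulate --sessions 5 --seed 1 --out sim/
halo analyze --subjects subjects.csv --out report/
```

`halo analyze` runs the pre/post study pipeline on a tidy subjects CSV
(`subject_id, condition, eye, vdi, brac_mg_per_l, pupil_mm`): mean ± SD
tables per condition, paired t tests, a split at the 0.25 mg/l breath
alcohol driving limit, and the deterioration-vs-BrAC regression with
scatter plot. `halometry.simulate_cohort` generates such a table from
the psychometric model, with drinking enlarging each subject's halo
radius in proportion to their breath alcohol content.

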