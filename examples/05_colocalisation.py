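"""Tumour-immune colocalisation via quadrat Morisita-Horn scoring.

Simulates clustered cancer/lymphocyte point patterns at three values of
the mixing parameter theta (the probability that a lymphocyte attaches
to a cancer cluster rather than an independent one) and scores each with
the Morisita-Horn index on a 250 µm quadrat grid.
"""

from panmorph import ColocSpec, colocalization, gen_point_pattern, immune_abundance

for theta in (0.0, 0.5, 1.0):
    spec = ColocSpec(theta=theta)
    cancer, lymph = gen_point_pattern(spec, seed=42)
    res = colocalization(cancer, lymph, width=250.0)
    print(
        f"theta = {theta:.1f}:  MH = {res.mh:.3f}  coloc100 = {res.coloc100:5.1f} "
        f"({res.n_quadrats} quadrats of {res.quadrat_width:.0f} µm)"
    )
print(
    "\nMH near 0 means lymphocytes occupy different quadrats than cancer"
    "\ncells (immune-excluded geometry); near 1 they share the same quadrats"
    "\n(infiltrated). coloc100 is the same score scaled to 0-100, the form"
    "\nused as a prognostic covariate."
)
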