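"""Run the full six-phase analysis on a synthetic video and print what the
instrument would report for this eye.

The pipeline selects usable frames, finds the pupil/iris, extracts the
inferior-iris region of interest, removes the iris colour and the
illumination tint, and assigns every pixel a lipid layer thickness by
nearest colour in the interference table.
"""

from lipilyzer import AnalysisConfig, analyze_sequence, build_lut, preset, render_video, write_outputs

lut = build_lut()
frames, _ = render_video(preset("patient2", seed=1), 75, lut)
result = analyze_sequence(frames, lut, AnalysisConfig())

s = result.summary
print(f"frames analyzed : {len(result.frame_stats)} (dropped: {len(result.dropped)})")
print(f"pooled LLT      : {s.mean_llt:.1f} +/- {s.sd_llt:.1f} nm over {s.n_pixels} pixels")
first = result.frame_stats[0]
print(f"first frame     : {first.mean_llt:.1f} +/- {first.sd_llt:.1f} nm, {first.n_pixels} px")
write_outputs(result, "analysis_output")
print("wrote stats.csv, histogram.json, surface/scatter CSVs to analysis_output/")
print("The video was generated with a true uniform thickness of 70 nm;")
print("a pooled mean within ~1 nm of that shows the colour inversion is unbiased.")
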