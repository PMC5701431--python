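"""Build the thickness -> RGB interference colour table and save it as CSV.

The table is the heart of the method: for each lipid thickness 0-240 nm
it gives the RGB colour that thin-film interference under a 6500 K white
LED would produce, which the analysis later inverts pixel by pixel.
"""

from lipilyzer import build_lut

lut = build_lut()
print("thickness_nm -> (R, G, B)")
for d in (0, 45, 70, 95, 120, 180, 240):
    r, g, b = lut.color_for(d)
    print(f"  {d:5d}       ({r:6.1f}, {g:6.1f}, {b:6.1f})")
lut.save("color_table.csv")
print("\nwrote all 241 entries to color_table.csv")
print("The d=0 entry is the darkest (a vanishing film reflects least);")
print("colours brighten through the 45-95 nm range that covers most eyes.")
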