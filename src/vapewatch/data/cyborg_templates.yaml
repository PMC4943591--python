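# Cyborg testimonial slot templates observed in e-cigarette marketing spam.
# Syntax: {a,b} alternation; (frag) optional; @USER any handle; BRAND any
# short token run; {#} any integer; URL any hyperlink.
templates:
  - id: quit-in-weeks
    pattern: "@USER {I,We} {tried,pursued} to {give up,quit} smoking. Discovered BRAND electronic cigarettes and quit in {#} weeks. {Marvelous,Amazing,Terrific}! URL"
  - id: really-easy
    pattern: "@USER It's now really easy to {quit,give up} smoking (cigarettes).—these BRAND electronic cigarettes are lots of {fun,pleasure}! URL"
  - id: assist-smokers
    pattern: "@USER electronic cigarettes can assist cigarette smokers to quit, it's well worth the cost URL"
  - id: incredible-method
    pattern: "@USER It's {incredible,amazing}—the (really) {easy,painless} {answer,method} to quit cigarette smoking through BRAND electronic cigarettes URL"
  - id: highly-recommend
    pattern: "I managed to quit smoking with these e-cigarettes, I highly recommend them: URL @USER"
  - id: after-years
    pattern: "@USER Its {amazing,extraordinary}—I (really) quit smoking after {#} yrs thanks to BRAND electronic cigarettes! URL"
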