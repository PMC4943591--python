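# Keyword configuration for e-cigarette tweet surveillance.
#
# ecig_patterns use the hyphen-optional "e(-)cig" notation: each expands to
# the "-", "", and " " joined variants and matches at substring level, so
# "e(-)cig" also fires on "ecigs" and "e-cigarette".
# "(frag)" elsewhere marks an optional fragment; both variants are expanded.

ecig_patterns:
  - "e(-)cig"
  - "e(-)cigarette"
  - "electronic cigarette"
  - "vape"
  - "vaping"

# Advertising jargon for the automation keyword tier (>= 3 hits => automated).
marketing_jargon:
  - "free trial"
  - "starter kit(s)"
  - "coupon(s)"
  - "buy"
  - "save"
  - "discount(s)"
  - "price"
  - "cost"
  - "deal"
  - "promo"
  - "money"
  - "sale"
  - "purchase"
  - "offer"
  - "review"
  - "code"
  - "win(ner)"
  - "free"
  - "premium"

topics:
  commercial:
    - "buy"
    - "save"
    - "coupon(s)"
    - "discount"
    - "price"
    - "cost"
    - "deal"
    - "promo"
    - "money"
    - "sale"
    - "purchase"
    - "offer"
    - "review"
    - "code"
    - "win(ner)"
    - "free"
    - "starter kit(s)"
    - "premium"
  cessation:
    - "quit"
    - "quitting"
    - "stop smoking"
    - "smoke free"
    - "safe"
    - "safer"
    - "safest"
  discount:
    - "free trial"
    - "coupon(s)"
    - "discount(s)"
    - "save"
    - "sale"
    - "free (e)lectronic (cig)arette"
  flavor:
    - "flavor(s)"
    - "flavour(s)"

# Popular e-liquid flavor names (folded into the flavor topic list).
flavors:
  - "menthol"
  - "mango"
  - "strawberry"
  - "vanilla"
  - "cherry"
  - "watermelon"
  - "bubble gum"
  - "gummy bear"
  - "cotton candy"
  - "chocolate"
  - "blueberry"
  - "peach"
  - "grape"
  - "apple pie"
  - "banana"
  - "caramel"
  - "coffee"
  - "mint"
  - "pineapple"
  - "raspberry"
  - "tutti frutti"
  - "butterscotch"
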