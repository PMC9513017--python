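term	keywords
dominos	pizza
pizza	pizza
pizzeria	pizza
mcdonalds	burger
burger king	burger
max burger	burger
sunset boulevard	burger
burger	burger
kfc	chicken
kylling	chicken
chicken	chicken
sushi	sushi
wok	asian
thai	asian
kebab	kebab;shawarma
shawarma	kebab;shawarma
durum	kebab
grill	grill;hotdog
grillbar	grill;hotdog
hotdog	hotdog;grill
pølse	hotdog;grill
bageri	bakery
bager	bakery
bakery	bakery
konditori	bakery
lagkagehuset	bakery
emmerys	bakery
café	coffee
cafe	coffee
coffee	coffee
kaffebar	coffee
espresso	coffee
starbucks	coffee
baresso	coffee
fisk	fish
fish	fish
slagter	meat
butcher	meat
frugt	produce
grønt	produce
minimarked	produce
kiosk	convenience
7 eleven	convenience
købmand	convenience
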