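branch_codes	term	match_mode	base_category
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	mcdonalds	substring	major_fastfood_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	sunset boulevard	substring	major_fastfood_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	burger king	substring	major_fastfood_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	kfc	token	major_fastfood_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	subway	substring	major_fastfood_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	dominos	substring	major_fastfood_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	max burger	substring	major_fastfood_chain
DD.56.10.99;DD.56.30.99	burger	token	nonchain_fastfood
DD.56.10.99;DD.56.30.99	pizza	token	nonchain_fastfood
DD.56.10.99;DD.56.30.99	pizzeria	substring	nonchain_fastfood
DD.56.10.99;DD.56.30.99	kebab	token	nonchain_fastfood
DD.56.10.99;DD.56.30.99	grill	substring	nonchain_fastfood
DD.56.10.99;DD.56.30.99	sushi	token	nonchain_fastfood
DD.56.10.99;DD.56.30.99	hotdog	token	nonchain_fastfood
DD.56.10.99;DD.56.30.99	pølse	substring	nonchain_fastfood
DD.56.10.99;DD.56.30.99	durum	token	nonchain_fastfood
DD.56.10.99;DD.56.30.99	takeaway	substring	takeaway_limited_seating
DD.56.10.99;DD.56.30.99	take away	substring	takeaway_limited_seating
DD.56.10.99;DD.56.30.99	shawarma	token	takeaway_limited_seating
DD.56.10.99;DD.56.30.99	wok	token	takeaway_limited_seating
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	lagkagehuset	substring	retail_bakery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	emmerys	substring	retail_bakery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	bodenhoffs	substring	retail_bakery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	reinh van haun	substring	retail_bakery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	farumhus	substring	retail_bakery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	meyers bageri	substring	retail_bakery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	laglace	substring	retail_bakery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	city bakery	substring	retail_bakery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	grannys house	substring	retail_bakery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	espresso house	substring	chain_coffee_shop
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	starbucks	substring	chain_coffee_shop
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	baresso	substring	chain_coffee_shop
DD.56.10.99;DD.56.30.99	coffee	token	chain_coffee_shop
DD.56.10.99;DD.56.30.99	kaffebar	substring	chain_coffee_shop
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	shell	token	petrol_kiosk
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	circle k	substring	petrol_kiosk
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	uno x	substring	petrol_kiosk
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	ok plus	substring	petrol_kiosk
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	q8	token	petrol_kiosk
DD.47.10.99;DD.47.20.99	kiosk	substring	petrol_kiosk
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	7 eleven	substring	convenience_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	nærkøb	substring	convenience_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	letkøb	substring	convenience_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	elite købmand	substring	convenience_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	shop n play	substring	convenience_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	dagligbrugsen	substring	grocery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	lokalbrugsen	substring	grocery_chain
DD.47.10.99;DD.47.20.99	brugsen	substring	grocery_chain
DD.47.10.99;DD.47.20.99	spar	token	grocery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	kwikspar	substring	grocery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	min købmand	substring	grocery_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	bilka	substring	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	kvickly	substring	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	superbrugsen	substring	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	irma	token	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	føtex	substring	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	superbest	substring	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	superspar	substring	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	eurospar	substring	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	løvbjerg	substring	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	abc lavpris	substring	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	meny	token	large_supermarket_chain
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	fakta	token	discount_supermarket
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	netto	token	discount_supermarket
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	kiwi	token	discount_supermarket
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	rema 1000	substring	discount_supermarket
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	rema1000	substring	discount_supermarket
DD.10.71.20;DD.47.10.99;DD.47.20.99;DD.47.22.00;DD.56.10.99;DD.56.30.99	aldi	token	discount_supermarket
DD.56.10.99;DD.56.30.99	restaurant	substring	traditional_restaurant
DD.56.10.99;DD.56.30.99	ristorante	substring	traditional_restaurant
DD.56.10.99;DD.56.30.99	trattoria	substring	traditional_restaurant
DD.56.10.99;DD.56.30.99	bistro	substring	traditional_restaurant
DD.56.10.99;DD.56.30.99	brasserie	substring	traditional_restaurant
DD.56.10.99;DD.56.30.99	noma	token	traditional_restaurant
DD.56.10.99;DD.56.30.99	café	token	cafe_allday
DD.56.10.99;DD.56.30.99	cafe	token	cafe_allday
DD.56.10.99;DD.56.30.99	cafeteria	substring	cafe_allday
DD.47.10.99;DD.47.20.99	frugt	token	fruit_vegetable_store
DD.47.10.99;DD.47.20.99	grønt	token	fruit_vegetable_store
DD.47.10.99;DD.47.20.99	minimarked	substring	fruit_vegetable_store
DD.10.71.20;DD.47.10.99;DD.47.20.99	bageri	substring	bakery
DD.10.71.20;DD.47.10.99;DD.47.20.99	konditori	substring	bakery
DD.10.71.20;DD.47.10.99;DD.47.20.99	bager	token	bakery
DD.47.22.00	slagter	substring	butcher
DD.47.22.00	kødbyen	substring	butcher
DD.47.22.00	fisk	substring	fishmonger
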